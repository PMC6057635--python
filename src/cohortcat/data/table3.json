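{
  "columns": [
    {"domain": "Socio-demographic and economic characteristics", "term": "Education"},
    {"domain": "Socio-demographic and economic characteristics", "term": "Income, possessions, and benefits"},
    {"domain": "Lifestyle and behaviours", "term": "Tobacco"},
    {"domain": "Lifestyle and behaviours", "term": "Alcohol"},
    {"domain": "Diseases", "term": "Pregnancy, childbirth and the puerperium (O00-O9A)"}
  ],
  "studies": [
    {
      "id": "AOBF",
      "name": "All Our Babies and All Our Families",
      "acronym": "AOB/F",
      "start_year": 2008,
      "populations": [
        {
          "id": "mothers",
          "name": "Mothers",
          "events": [
            {"id": "gest24w", "name": "24 weeks gestation", "counts": [4, 8, 5, 14, 0]},
            {"id": "gest36w", "name": "36 weeks gestation", "counts": [0, 3, 7, 9, 0]},
            {"id": "pp4m", "name": "4 months postpartum", "counts": [0, 6, 5, 4, 0]},
            {"id": "pp1y", "name": "1 year postpartum", "counts": [0, 8, 5, 4, 0]},
            {"id": "pp3y", "name": "3 years postpartum", "counts": [1, 2, 5, 4, 0]}
          ]
        },
        {
          "id": "children",
          "name": "Children",
          "events": [
            {"id": "pp1y", "name": "1 year postpartum", "counts": [0, 2, 0, 0, 0]}
          ]
        }
      ]
    },
    {
      "id": "APrON",
      "name": "Alberta Pregnancy Outcomes and Nutrition",
      "acronym": "APrON",
      "start_year": 2009,
      "populations": [
        {
          "id": "mothers",
          "name": "Mothers",
          "events": [
            {"id": "tri1", "name": "First trimester", "counts": [1, 1, 15, 15, 49]},
            {"id": "tri2", "name": "Second trimester", "counts": [0, 0, 7, 5, 35]},
            {"id": "tri3", "name": "Third trimester", "counts": [0, 7, 6, 6, 29]},
            {"id": "pp12w", "name": "12 weeks postpartum", "counts": [0, 0, 6, 6, 34]},
            {"id": "pp24w", "name": "24 weeks postpartum", "counts": [0, 0, 2, 2, 0]},
            {"id": "pp12m", "name": "12 months postpartum", "counts": [0, 0, 3, 3, 0]}
          ]
        },
        {
          "id": "partners",
          "name": "Partners",
          "events": [
            {"id": "tri2", "name": "Second trimester", "counts": [1, 0, 4, 3, 0]},
            {"id": "pp12w", "name": "12 weeks postpartum", "counts": [0, 0, 3, 2, 0]}
          ]
        },
        {
          "id": "children",
          "name": "Children",
          "events": [
            {"id": "pp12w", "name": "12 weeks postpartum", "counts": [0, 0, 0, 0, 1]}
          ]
        }
      ]
    }
  ]
}
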