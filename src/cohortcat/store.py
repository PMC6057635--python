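"""Catalogue directory layout shared by the CLI, generators and tests.

::

    <catalogue-dir>/
      taxonomy.yaml            optional; packaged taxonomy used when absent
      studies/<id>.yaml        one YAML document per study
      datasets/<id>/
        dataset.yaml           id, name, description, link, annotations
        variables.csv          plain_csv dialect
        categories.csv         plain_csv dialect (may be absent)

Annotations live in dataset.yaml (``annotations: {var: ["Domain/Term"]}``) so
the CSV files remain pure dictionary-dialect artifacts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .dictionary_io import DIALECTS, read_dictionary, write_dictionary
from .model import Dataset, Study, dataset_from_dict, dataset_to_dict, dump_study_yaml, load_study_yaml
from .taxonomy import Taxonomy, builtin_taxonomy, load_taxonomy, save_taxonomy

__all__ = ["read_catalogue_dir", "write_catalogue_dir"]


def read_catalogue_dir(path: str | Path) -> tuple[list[Study], list[Dataset], Taxonomy]:
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"catalogue directory not found: {root}")
    studies = [
        load_study_yaml(f.read_text("utf-8")) for f in sorted((root / "studies").glob("*.yaml"))
    ]
    datasets: list[Dataset] = []
    ds_root = root / "datasets"
    if ds_root.is_dir():
        for ds_dir in sorted(p for p in ds_root.iterdir() if p.is_dir()):
            meta = yaml.safe_load((ds_dir / "dataset.yaml").read_text("utf-8"))
            cats_file = ds_dir / "categories.csv"
            parsed = read_dictionary(
                (ds_dir / "variables.csv").read_text("utf-8"),
                cats_file.read_text("utf-8") if cats_file.exists() else None,
                DIALECTS["plain_csv"],
            )
            datasets.append(dataset_from_dict(meta, parsed.variables))
    tax_file = root / "taxonomy.yaml"
    taxonomy = (
        load_taxonomy(tax_file.read_text("utf-8")) if tax_file.exists() else builtin_taxonomy()
    )
    return studies, datasets, taxonomy


def write_catalogue_dir(
    path: str | Path,
    studies: list[Study],
    datasets: list[Dataset],
    taxonomy: Optional[Taxonomy] = None,
) -> Path:
    root = Path(path)
    (root / "studies").mkdir(parents=True, exist_ok=True)
    for study in studies:
        (root / "studies" / f"{study.id}.yaml").write_text(dump_study_yaml(study), "utf-8")
    for ds in datasets:
        ds_dir = root / "datasets" / ds.id
        ds_dir.mkdir(parents=True, exist_ok=True)
        (ds_dir / "dataset.yaml").write_text(
            yaml.safe_dump(dataset_to_dict(ds), sort_keys=False, allow_unicode=True), "utf-8"
        )
        variables_csv, categories_csv = write_dictionary(ds, DIALECTS["plain_csv"])
        (ds_dir / "variables.csv").write_text(variables_csv, "utf-8")
        (ds_dir / "categories.csv").write_text(categories_csv, "utf-8")
    if taxonomy is not None:
        (root / "taxonomy.yaml").write_text(save_taxonomy(taxonomy), "utf-8")
    return root
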