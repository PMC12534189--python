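"""CSV round-tripping for catalogues and formulation tables.

Formulation tables use one row per formulation with semicolon-joined
component ids and molar percentages, plus ``label:<task>`` columns for
efficacy labels.  Molar percentages are written with enough precision
to round-trip decimal strings of up to six fractional digits.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .formulation import Catalogue, ComponentClass, Formulation, MoleculeRecord

LABEL_PREFIX = "label:"


def read_catalogue(path: str | Path) -> Catalogue:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        amine = row.get("amine_count")
        mw = row.get("molar_mass")
        records.append(
            MoleculeRecord(
                id=str(row["id"]),
                smiles=str(row["smiles"]),
                component_class=ComponentClass(row["component_class"]),
                amine_count=None if amine is None or pd.isna(amine) else int(amine),
                molar_mass=None if mw is None or pd.isna(mw) else float(mw),
            )
        )
    return Catalogue(records)


def write_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    catalogue.to_frame().to_csv(path, index=False)


def formulations_to_frame(formulations: list[Formulation]) -> pd.DataFrame:
    tasks = sorted({t for f in formulations for t in f.labels})
    rows = []
    for i, f in enumerate(formulations):
        row = {
            "formulation_id": f.id if f.id is not None else f"F{i:06d}",
            "component_ids": ";".join(f.molecule_ids),
            "molar_percents": ";".join(_fmt(p) for p in f.molar_percents),
            "np_ratio": f.np_ratio,
            "weight_ratio": f.il_rna_weight_ratio,
            "aq_org_ratio": f.aqueous_organic_ratio,
        }
        for t in tasks:
            row[LABEL_PREFIX + t] = f.labels.get(t)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_formulations(df: pd.DataFrame) -> list[Formulation]:
    label_cols = [c for c in df.columns if c.startswith(LABEL_PREFIX)]
    out = []
    for _, row in df.iterrows():
        ids = str(row["component_ids"]).split(";")
        pcts = [float(p) for p in str(row["molar_percents"]).split(";")]
        labels = {}
        for c in label_cols:
            v = row[c]
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                labels[c[len(LABEL_PREFIX):]] = float(v)
        np_ratio = row.get("np_ratio")
        wr = row.get("weight_ratio")
        out.append(
            Formulation(
                components=tuple(zip(ids, pcts)),
                np_ratio=None if np_ratio is None or pd.isna(np_ratio) else float(np_ratio),
                il_rna_weight_ratio=None if wr is None or pd.isna(wr) else float(wr),
                aqueous_organic_ratio=str(row["aq_org_ratio"]),
                labels=labels,
                id=str(row["formulation_id"]),
            )
        )
    return out


def write_formulations(formulations: list[Formulation], path: str | Path) -> None:
    formulations_to_frame(formulations).to_csv(path, index=False)


def read_formulations(path: str | Path) -> list[Formulation]:
    return frame_to_formulations(pd.read_csv(path))


def _fmt(p: float) -> str:
    # repr keeps <=6-fractional-digit decimals exact through the round trip
    s = f"{p:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"
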