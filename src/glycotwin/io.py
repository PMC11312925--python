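"""Plain-text readers/writers for cohort tables and the truth sidecar."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["write_sample_sheet", "read_sample_sheet", "write_phenotypes",
           "read_phenotypes", "write_truth_json", "read_truth_json"]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    cols = ["individual_id", "family_id", "zygosity", "sex", "age", "plate"]
    samples[cols].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual_id": str,
                                              "family_id": str,
                                              "zygosity": str,
                                              "plate": str})


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    out.index.name = out.index.name or "individual_id"
    out.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.to_dict(orient="split")}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth_json(truth: dict, path) -> None:
    """Sidecar of all generative parameters for a simulated cohort."""
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
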