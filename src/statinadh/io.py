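"""Plain-CSV readers/writers for the analytical-dataset layout.

A dataset directory holds one file per data role (claims, demographics,
ground truth when simulated, config) plus a small manifest mapping roles to
filenames, so externally supplied datasets with different filenames can be
read by editing the manifest rather than the code.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_dataset", "read_dataset", "read_analytical_dataset",
           "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.json"

_DEFAULT_FILES = {
    "claims": "claims.csv",
    "demographics": "demographics.csv",
    "truth": "truth.csv",
    "true_loadings": "true_loadings.csv",
}

_CLAIM_COLUMNS = ["patient_id", "month", "kind", "code", "value",
                  "days_supply", "strength", "new_refill_flag"]


def write_dataset(out_dir, claims: pd.DataFrame, demographics: pd.DataFrame,
                  truth: pd.DataFrame | None = None,
                  true_loadings: pd.DataFrame | None = None,
                  config=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    claims[_CLAIM_COLUMNS].to_csv(out / _DEFAULT_FILES["claims"], index=False)
    manifest["claims"] = _DEFAULT_FILES["claims"]
    demographics.to_csv(out / _DEFAULT_FILES["demographics"], index=False)
    manifest["demographics"] = _DEFAULT_FILES["demographics"]
    if truth is not None:
        truth.to_csv(out / _DEFAULT_FILES["truth"], index=False)
        manifest["truth"] = _DEFAULT_FILES["truth"]
    if true_loadings is not None:
        true_loadings.to_csv(out / _DEFAULT_FILES["true_loadings"])
        manifest["true_loadings"] = _DEFAULT_FILES["true_loadings"]
    if config is not None:
        config.to_yaml(out / "config.yaml")
        manifest["config"] = "config.yaml"
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _read_claims(path) -> pd.DataFrame:
    claims = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    claims["month"] = claims["month"].astype(int)
    claims["new_refill_flag"] = claims["new_refill_flag"].map(
        {True: True, False: False, "True": True, "False": False}).astype(object)
    drug = claims["kind"] == "drug"
    lab = claims["kind"] == "lab"
    if (claims.loc[drug, "days_supply"].isna()).any():
        raise ValueError("drug claim without days_supply")
    if (claims.loc[lab, "value"].isna()).any():
        raise ValueError("lab claim without value")
    if (claims.loc[drug, "days_supply"] < 0).any():
        raise ValueError("negative days_supply in claims")
    return claims


def read_dataset(in_dir) -> dict:
    """Read a dataset directory back into typed tables.

    Validates the manifest, claim-event field invariants, unique patient ids
    in demographics, and id consistency between claims and demographics.
    """
    in_dir = Path(in_dir)
    mpath = in_dir / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    for role in ("claims", "demographics"):
        if role not in manifest:
            raise FileNotFoundError(f"manifest lacks required role '{role}'")
        if not (in_dir / manifest[role]).exists():
            raise FileNotFoundError(f"missing file for role '{role}': {manifest[role]}")
    out = {"claims": _read_claims(in_dir / manifest["claims"])}
    demo = pd.read_csv(in_dir / manifest["demographics"], dtype={"patient_id": str})
    dup = demo["patient_id"][demo["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated patient id(s) in demographics: {sorted(set(dup))[:5]}")
    out["demographics"] = demo
    unknown = set(out["claims"]["patient_id"]) - set(demo["patient_id"])
    if unknown:
        raise ValueError(f"claims reference ids absent from demographics: {sorted(unknown)[:5]}")
    for role in ("truth", "true_loadings"):
        if role in manifest and (in_dir / manifest[role]).exists():
            out[role] = pd.read_csv(in_dir / manifest[role])
    return out


# an externally supplied analytical dataset and the simulator export share
# one layout and therefore one reader
read_analytical_dataset = read_dataset
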