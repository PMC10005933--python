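"""Reading, writing and validation of participant/feature tables.

All artifacts are plain text: CSV/TSV tables with a header row and JSON
sidecars.  Feature columns follow the ``<MODALITY>__<region>`` naming
convention; floats are serialized at full round-trip precision (17
significant digits) so write-then-read is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import MODALITIES

PARTICIPANT_COLUMNS = (
    "participant_id", "group", "diagnosis", "age_months", "sex",
    "race_ethnicity", "site", "family_id", "tiv",
)

FLOAT_FORMAT = "%.17g"


class ValidationError(ValueError):
    """Input table failed validation; message lists the offending items."""


def write_tables(participants: pd.DataFrame, features: pd.DataFrame,
                 out_dir, schema=None, spec=None) -> dict[str, Path]:
    """Write both tables (CSV) plus a JSON sidecar describing the generation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "features": out / "features.csv",
        "sidecar": out / "cohort_schema.json",
    }
    participants.to_csv(paths["participants"], index=False,
                        float_format=FLOAT_FORMAT)
    features.to_csv(paths["features"], index=False, float_format=FLOAT_FORMAT)
    sidecar = {}
    if schema is not None:
        sidecar["schema"] = schema.to_dict()
    if spec is not None:
        sidecar["generation_spec"] = spec.to_dict()
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    # round_trip parsing keeps the 17-digit serialization exact
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_tables(participants_path, features_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a (ParticipantTable, FeatureTable) pair."""
    part = _read_table(participants_path)
    feat = _read_table(features_path)
    validate_tables(part, feat)
    return part, feat


def validate_tables(participants: pd.DataFrame, features: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on malformed inputs."""
    missing = [c for c in PARTICIPANT_COLUMNS if c not in participants.columns]
    if missing:
        raise ValidationError(f"participants table missing columns: {missing}")
    ids = participants["participant_id"]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise ValidationError(f"duplicate participant ids: {dups}")
    bad_groups = set(participants["group"]) - {"reference", "clinical"}
    if bad_groups:
        raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")

    if "participant_id" not in features.columns:
        raise ValidationError("feature table missing participant_id column")
    unknown_ids = set(features["participant_id"]) - set(ids)
    if unknown_ids:
        raise ValidationError(
            f"feature table ids absent from participants: {sorted(unknown_ids)}")
    feat_cols = [c for c in features.columns if c != "participant_id"]
    bad_cols = []
    for c in feat_cols:
        parts = c.split("__", 1)
        if len(parts) != 2 or parts[0] not in MODALITIES:
            bad_cols.append(c)
    if bad_cols:
        raise ValidationError(
            f"feature columns with unknown modality prefix: {bad_cols}")
    values = features[feat_cols]
    if values.isna().any().any():
        holes = [
            (str(features.loc[i, "participant_id"]), c)
            for c in feat_cols for i in values.index[values[c].isna()]
        ]
        raise ValidationError(f"missing feature values at (id, column): {holes[:20]}")
    non_numeric = [c for c in feat_cols
                   if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"non-numeric feature columns: {non_numeric}")
    if not np.isfinite(values.to_numpy(float)).all():
        raise ValidationError("non-finite feature values present")

    sub = participants.get("true_subtype")
    if sub is not None:
        ref = participants["group"] == "reference"
        if sub[ref].notna().any():
            raise ValidationError("reference participants must have null true_subtype")
        if sub[~ref].isna().any():
            raise ValidationError("clinical participants must carry a true_subtype")


def validate_group_manifest(manifest: dict) -> int:
    """Check a clinical group-size manifest for internal consistency.

    ``manifest`` maps clinical category names to participant counts and may
    carry a ``"total"`` entry; the categories must be nonnegative integers
    and, when a total is declared, must sum to it exactly.  Returns the
    clinical total.
    """
    counts = {k: v for k, v in manifest.items() if k != "total"}
    bad = {k: v for k, v in counts.items()
           if not isinstance(v, (int, np.integer)) or v < 0}
    if bad:
        raise ValidationError(f"counts must be nonnegative integers: {bad}")
    total = int(sum(counts.values()))
    if "total" in manifest and int(manifest["total"]) != total:
        raise ValidationError(
            f"category counts sum to {total}, manifest declares {manifest['total']}")
    return total


def write_labels(labels: pd.Series, path) -> None:
    """Write subtype labels as a two-column TSV (participant_id, subtype)."""
    df = pd.DataFrame({"participant_id": labels.index, "subtype": labels.values})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["subtype"].to_numpy(), index=df["participant_id"],
                     name="subtype")


def write_comparison_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
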