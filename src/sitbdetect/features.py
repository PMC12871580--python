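"""Design matrices for the ten named feature sets.

The comparison spans three data modalities: four structured sets in
increasing dimensionality (codes/chief-concern only; plus the gatekept
suicide-screening items or the mental-health diagnosis categories; and
augmented case surveillance, aCS, holding every structured field), three
text-score sets (one column each), and three hybrid sets (aCS columns plus
one text-score column).

Missingness encoding follows the screening-questionnaire rule throughout:
a missing numeric value contributes 0 to the value column plus a 1 in a
paired missing-indicator column, so the gatekept "not administered" state
stays visible to the classifier.  Categorical fields are one-hot encoded
with an explicit ``unknown`` level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .synthetic_ehr import (
    CSSRS_N_ITEMS,
    DX_CATEGORIES,
    RACE_CATEGORIES,
    INSURANCE_CATEGORIES,
    DISPOSITION_CATEGORIES,
)

__all__ = [
    "FeatureSetId",
    "FeatureMatrix",
    "DataError",
    "UsageError",
    "encode_cssrs_missingness",
    "build_feature_matrix",
    "write_feature_matrix",
    "TEXT_MODALITY",
]


class DataError(ValueError):
    """Malformed input data (unknown states, bad values)."""


class UsageError(ValueError):
    """API contract violation (missing inputs, unknown identifiers)."""


class FeatureSetId(str, Enum):
    """Closed enumeration of the ten compared feature sets."""

    ICD_CC = "ICD_CC"
    CSSRS_ICD_CC = "CSSRS_ICD_CC"
    MHDX_ICD_CC = "MHDX_ICD_CC"
    ACS = "ACS"
    NLP_GENERAL = "NLP_GENERAL"
    NLP_MED = "NLP_MED"
    LLM = "LLM"
    ACS_NLP_GENERAL = "ACS_NLP_GENERAL"
    ACS_NLP_MED = "ACS_NLP_MED"
    ACS_LLM = "ACS_LLM"


STRUCTURED_SETS = frozenset(
    {FeatureSetId.ICD_CC, FeatureSetId.CSSRS_ICD_CC, FeatureSetId.MHDX_ICD_CC, FeatureSetId.ACS}
)
TEXT_SETS = frozenset({FeatureSetId.NLP_GENERAL, FeatureSetId.NLP_MED, FeatureSetId.LLM})
HYBRID_SETS = frozenset(
    {FeatureSetId.ACS_NLP_GENERAL, FeatureSetId.ACS_NLP_MED, FeatureSetId.ACS_LLM}
)

#: text modality feeding each text / hybrid feature set
TEXT_MODALITY = {
    FeatureSetId.NLP_GENERAL: "knn_general",
    FeatureSetId.NLP_MED: "knn_medical",
    FeatureSetId.LLM: "likert",
    FeatureSetId.ACS_NLP_GENERAL: "knn_general",
    FeatureSetId.ACS_NLP_MED: "knn_medical",
    FeatureSetId.ACS_LLM: "likert",
}


@dataclass
class FeatureMatrix:
    encounter_ids: list[str]
    column_names: list[str]
    provenance: list[str]  # per column: structured | missing-indicator | text-score
    X: np.ndarray
    feature_set_id: FeatureSetId

    def __post_init__(self) -> None:
        assert self.X.shape == (len(self.encounter_ids), len(self.column_names))
        assert len(self.provenance) == len(self.column_names)
        if np.isnan(self.X).any():
            raise DataError("feature matrix contains missing cells after encoding")

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "encounter_id", self.encounter_ids)
        return df


_CSSRS_STATES = {"positive", "negative", "missing"}


def encode_cssrs_missingness(items) -> tuple[np.ndarray, np.ndarray]:
    """Encode one gatekept screening vector into (values, indicators).

    Each item becomes two numbers: value (positive -> 1, negative or
    missing -> 0) and a missing indicator (missing -> 1 else 0), so the
    clinical decision not to administer deeper items remains encoded.
    """
    values, indicators = [], []
    for it in items:
        if it not in _CSSRS_STATES:
            raise DataError(f"unknown c-SSRS item state: {it!r}")
        values.append(1.0 if it == "positive" else 0.0)
        indicators.append(1.0 if it == "missing" else 0.0)
    return np.asarray(values), np.asarray(indicators)


def _onehot(series: pd.Series, categories, prefix: str) -> tuple[list[str], np.ndarray]:
    """One-hot with an explicit trailing ``unknown`` level for NaN/unseen."""
    cats = list(categories) + ["unknown"]
    vals = series.astype(object).where(series.notna(), "unknown")
    vals = vals.where(vals.isin(cats), "unknown")
    cols = [f"{prefix}_{c}" for c in cats]
    X = np.zeros((len(series), len(cats)))
    for j, c in enumerate(cats):
        X[:, j] = (vals == c).to_numpy(dtype=float)
    return cols, X


def _numeric_with_indicator(series: pd.Series, name: str):
    """Missing numerics: 0 in the value column, 1 in a paired indicator."""
    x = pd.to_numeric(series, errors="coerce")
    miss = x.isna().to_numpy(dtype=float)
    vals = x.fillna(0.0).to_numpy(dtype=float)
    return [name, f"{name}_missing"], np.column_stack([vals, miss]), ["structured", "missing-indicator"]


def _icd_cc_block(df: pd.DataFrame):
    cols = ["sitb_icd_flag", "sitb_chief_concern_flag", "mh_chief_concern_flag"]
    X = df[cols].to_numpy(dtype=float)
    return cols, X, ["structured"] * 3


def _cssrs_block(df: pd.DataFrame):
    names, blocks, prov = [], [], []
    for i in range(1, CSSRS_N_ITEMS + 1):
        col = df[f"cssrs_item{i}"]
        states = col.astype(object).where(col.notna(), "missing")
        bad = set(states.unique()) - _CSSRS_STATES
        if bad:
            raise DataError(f"unknown c-SSRS item state(s): {sorted(bad)!r}")
        values = (states == "positive").to_numpy(dtype=float)
        missing = (states == "missing").to_numpy(dtype=float)
        names += [f"cssrs_item{i}", f"cssrs_item{i}_missing"]
        blocks += [values, missing]
        prov += ["structured", "missing-indicator"]
    return names, np.column_stack(blocks), prov


def _mhdx_block(df: pd.DataFrame):
    cols = [f"dx_{c}" for c in DX_CATEGORIES]
    return cols, df[cols].to_numpy(dtype=float), ["structured"] * len(cols)


def _acs_extra_block(df: pd.DataFrame):
    """All remaining structured fields beyond the ICD/CC, c-SSRS and dx blocks."""
    names: list[str] = []
    blocks: list[np.ndarray] = []
    prov: list[str] = []

    names.append("age_years")
    blocks.append(df["age_years"].to_numpy(dtype=float))
    prov.append("structured")
    names.append("is_child")
    blocks.append((df["age_group"] == "child").to_numpy(dtype=float))
    prov.append("structured")

    for prefix, cats in (
        ("sex", ("female", "male")),
        ("race", RACE_CATEGORIES),
        ("insurance", INSURANCE_CATEGORIES),
        ("disposition", DISPOSITION_CATEGORIES),
    ):
        src = {"sex": "sex", "race": "race_ethnicity",
               "insurance": "insurance", "disposition": "disposition"}[prefix]
        c, X = _onehot(df[src], cats, prefix)
        names += c
        blocks += [X[:, j] for j in range(X.shape[1])]
        prov += ["structured"] * len(c)

    for flag in (
        "psychotropic_med_flag",
        "homicidal_ideation_flag",
        "overdose_lab_flag",
        "urine_drug_positive_flag",
    ):
        names.append(flag)
        blocks.append(df[flag].to_numpy(dtype=float))
        prov.append("structured")

    for base in ("prior_ed_visits", "prior_psych_hosp", "prior_medical_hosp"):
        for w in ("30d", "90d", "365d"):
            col = f"{base}_{w}"
            names.append(col)
            blocks.append(df[col].to_numpy(dtype=float))
            prov.append("structured")

    for col in ("svi", "adi"):
        n, X, p = _numeric_with_indicator(df[col], col)
        names += n
        blocks += [X[:, 0], X[:, 1]]
        prov += p

    return names, np.column_stack(blocks), prov


def _structured_blocks(df: pd.DataFrame, fsid: FeatureSetId):
    names, prov = [], []
    mats = []
    if fsid in TEXT_SETS:
        return names, None, prov
    for block in (_icd_cc_block,) + (
        (_cssrs_block,) if fsid in (FeatureSetId.CSSRS_ICD_CC,) else ()
    ) + (
        (_mhdx_block,) if fsid in (FeatureSetId.MHDX_ICD_CC,) else ()
    ):
        n, X, p = block(df)
        names += n
        mats.append(X)
        prov += p
    if fsid in {FeatureSetId.ACS} | HYBRID_SETS:
        for block in (_cssrs_block, _mhdx_block, _acs_extra_block):
            n, X, p = block(df)
            names += n
            mats.append(X)
            prov += p
    return names, np.column_stack(mats), prov


def build_feature_matrix(
    encounters: pd.DataFrame,
    feature_set_id: FeatureSetId | str,
    text_scores: dict[str, float] | pd.Series | None = None,
) -> FeatureMatrix:
    """Build the numeric design matrix for one named feature set.

    ``encounters`` is the flat encounter table (generator dialect).
    ``text_scores`` maps encounter id to the encounter-level text score of
    the modality the feature set requires; it is mandatory exactly for the
    text and hybrid sets and must cover every encounter.
    """
    try:
        fsid = FeatureSetId(feature_set_id)
    except ValueError as exc:
        raise UsageError(f"unknown feature set id: {feature_set_id!r}") from exc

    ids = encounters["encounter_id"].astype(str).tolist()
    needs_text = fsid in TEXT_SETS or fsid in HYBRID_SETS
    if needs_text:
        if text_scores is None:
            raise UsageError(f"{fsid.value} requires text_scores")
        scores = pd.Series(text_scores)
        missing = [i for i in ids if i not in scores.index]
        if missing:
            raise UsageError(
                f"text_scores missing for {len(missing)} encounters (e.g. {missing[:3]})"
            )
        score_col = scores.reindex(ids).to_numpy(dtype=float)
    elif text_scores is not None:
        raise UsageError(f"{fsid.value} is structured-only; text_scores not accepted")

    names, X, prov = _structured_blocks(encounters, fsid)
    if needs_text:
        modality = TEXT_MODALITY[fsid]
        score_name = f"text_score_{modality}"
        if X is None:
            names, X, prov = [score_name], score_col[:, None], ["text-score"]
        else:
            names = names + [score_name]
            X = np.column_stack([X, score_col])
            prov = prov + ["text-score"]
    return FeatureMatrix(ids, names, prov, np.asarray(X, dtype=float), fsid)


def write_feature_matrix(fm: FeatureMatrix, csv_path: str | Path) -> None:
    """Write the matrix as CSV plus a sidecar JSON column-provenance manifest."""
    csv_path = Path(csv_path)
    fm.to_frame().to_csv(csv_path, index=False)
    manifest = {
        "feature_set_id": fm.feature_set_id.value,
        "n_rows": len(fm.encounter_ids),
        "columns": [
            {"name": n, "provenance": p}
            for n, p in zip(fm.column_names, fm.provenance)
        ],
    }
    csv_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
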