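"""VASARI qualitative feature schema, recoding and model encoding.

The raw radiologist-scored table is recoded with a declared, versioned map
(multi-category items collapsed at clinically natural cut-points; continuous
sizes kept numeric), then dummy-coded against explicit reference levels for
use in Cox / classification models. The recoding map is data, not code: a
user-supplied JSON map replaces the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# category sets after recoding; first level of each list is the reference
SCHEMA: dict[str, list] = {
    "eloquent_cortex": [0, 1],
    "multifocality": [0, 1],
    "subependymal_extension": [0, 1],
    "edema_proportion": ["low", "medium", "high"],  # ordinal, low = reference
    "t1_flair_ratio": ["normal", "increased"],
    "enhancing_margin": ["thin", "thick"],
    "hemorrhage": [0, 1],
    "pial_invasion": [0, 1],
    "deep_wm_invasion": [0, 1],
    "midline_cross": [0, 1],
    "location": ["frontal", "temporal", "parietal", "occipital"],
}
NUMERIC_COLUMNS = [
    "major_axis_mm", "minor_axis_mm", "proportion_necrosis", "proportion_non_enhancing",
]

# default recoding: raw category -> coded group, per column
DEFAULT_RECODING_MAP: dict[str, dict] = {
    "edema_proportion": {"none": "low", "low": "low", "medium": "medium", "high": "high"},
    "t1_flair_ratio": {"normal": "normal", "decreased": "normal", "increased": "increased"},
    "enhancing_margin": {"thin": "thin", "thick": "thick", "solid": "thick"},
}
RECODING_MAP_VERSION = "1.0"


def recode(raw: pd.DataFrame, recoding_map: dict | None = None) -> pd.DataFrame:
    """Recode a raw VASARI table to the declared schema. Unknown categories
    become missing (with a log entry); already-coded values pass through, so
    the operation is idempotent."""
    missing_cols = [c for c in list(SCHEMA) + NUMERIC_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise KeyError(f"raw VASARI table lacks required columns: {missing_cols}")
    rmap = DEFAULT_RECODING_MAP if recoding_map is None else recoding_map
    out = raw.copy()
    for col, levels in SCHEMA.items():
        colmap = rmap.get(col, {})
        def _code(v, colmap=colmap, levels=levels, col=col):
            if pd.isna(v):
                return np.nan
            if v in colmap:
                v = colmap[v]
            if v in levels:
                return v
            log.warning("unknown category %r in column %s -> missing", v, col)
            return np.nan
        out[col] = out[col].map(_code)
        if out[col].isna().all():
            log.warning("VASARI column %s is entirely missing after recoding", col)
    for col in NUMERIC_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out[list(SCHEMA) + NUMERIC_COLUMNS]


def encode_for_model(
    records: pd.DataFrame, reference_levels: dict[str, object] | None = None
) -> pd.DataFrame:
    """Treatment (reference-level) dummy coding of a recoded table.

    Ordinal edema expands to medium/high indicators against the low
    reference. Unseen levels raise (they indicate a validation-time schema
    drift). Numeric columns pass through unchanged."""
    refs = {col: levels[0] for col, levels in SCHEMA.items()}
    if reference_levels:
        refs.update(reference_levels)
    pieces = []
    for col, levels in SCHEMA.items():
        vals = records[col]
        seen = set(vals.dropna().unique())
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unseen level(s) {sorted(map(str, unknown))} in column {col}")
        ref = refs[col]
        for lv in levels:
            if lv == ref:
                continue
            name = f"{col}_{lv}" if len(levels) > 2 else col
            ind = (vals == lv).astype(float)
            ind[vals.isna()] = np.nan
            pieces.append(ind.rename(name))
    for col in NUMERIC_COLUMNS:
        pieces.append(records[col].astype(float))
    return pd.concat(pieces, axis=1)


def decode_row(row: pd.Series) -> dict:
    """Inverse of `encode_for_model` for a complete-case design row."""
    rec: dict = {}
    for col, levels in SCHEMA.items():
        if len(levels) == 2:
            rec[col] = levels[1] if row[col] == 1 else levels[0]
        else:
            chosen = levels[0]
            for lv in levels[1:]:
                if row[f"{col}_{lv}"] == 1:
                    chosen = lv
            rec[col] = chosen
    for col in NUMERIC_COLUMNS:
        rec[col] = float(row[col])
    return rec
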