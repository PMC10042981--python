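"""Shared containers and table validators.

Tables are plain :class:`pandas.DataFrame` objects with documented columns;
the only bespoke container is :class:`AbundanceMatrix`, a samples x compounds
matrix that carries its measurement scale so downstream stages can refuse
input at the wrong stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CULTIVATION_METHODS = ("open_field", "mini_tunnel", "heated_field", "greenhouse")

SAMPLE_COLUMNS = [
    "sample_id",
    "variety",
    "cultivation",
    "harvest_week_index",
    "calendar_week",
    "replicate",
    "batch",
    "injection_order",
    "is_qc",
]

COMPOUND_COLUMNS = [
    "compound_id",
    "platform",
    "annotation",
    "chemical_class",
    "loi",
    "flavour_flag",
]

#: measurement scales an AbundanceMatrix can carry, in pipeline order
SCALES = ("raw", "log2", "corrected", "pareto")


@dataclass
class AbundanceMatrix:
    """Samples x compounds intensity matrix with an explicit scale flag.

    Parameters
    ----------
    data:
        DataFrame indexed by sample_id with compound_id columns. Missing
        measurements are NaN.
    scale:
        One of ``raw`` (positive relative intensities), ``log2``,
        ``corrected`` (log2 after QC correction) or ``pareto``.
    """

    data: pd.DataFrame
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.scale == "raw":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                bad = self.data.columns[(self.data < 0).any(axis=0)].tolist()
                raise ValidationError(f"raw intensities must be >= 0; negative values in columns {bad[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def compounds(self) -> pd.Index:
        return self.data.columns

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return replace(self, data=data, scale=self.scale if scale is None else scale)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale, dict(self.meta))


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check SampleTable structure; returns the (possibly re-typed) table."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id values: {dups[:5]}")
    for batch, grp in samples.groupby("batch"):
        if grp["injection_order"].duplicated().any():
            raise ValidationError(f"injection_order not unique within batch {batch!r}")
    bio = samples[~samples["is_qc"].astype(bool)]
    bad_cult = set(bio["cultivation"]) - set(CULTIVATION_METHODS)
    if bad_cult:
        raise ValidationError(f"unknown cultivation methods: {sorted(bad_cult)}")
    if (bio["harvest_week_index"].astype(float) < 1).any():
        raise ValidationError("harvest_week_index must be >= 1 for biological samples")
    return samples


def validate_compound_table(compounds: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COMPOUND_COLUMNS if c not in compounds.columns]
    if missing:
        raise ValidationError(f"compound table missing columns: {missing}")
    if compounds["compound_id"].duplicated().any():
        dups = compounds.loc[compounds["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValidationError(f"duplicated compound_id values: {dups[:5]}")
    bad_loi = set(compounds["loi"].astype(int)) - {1, 2, 3, 4}
    if bad_loi:
        raise ValidationError(f"loi must be in 1..4; found {sorted(bad_loi)}")
    bad_platform = set(compounds["platform"]) - {"GCMS", "LCMS"}
    if bad_platform:
        raise ValidationError(f"platform must be GCMS or LCMS; found {sorted(bad_platform)}")
    return compounds


def biological_mask(samples: pd.DataFrame) -> pd.Series:
    """Boolean mask of non-QC rows, indexed like ``samples``."""
    return ~samples["is_qc"].astype(bool)
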