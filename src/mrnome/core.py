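"""Data model and I/O for two-sample summary-data Mendelian randomization.

The universal input is a table with one row per genetic variant holding the
SNP-exposure association estimate and its standard error (from the exposure
GWAS) and the SNP-outcome association estimate and its standard error (from
an independent outcome GWAS).  Variants are assumed uncorrelated (LD-pruned
upstream); no allele-letter harmonization is performed here — the only coding
operation supported is :func:`orient_exposure_positive`, which recodes alleles
so that every SNP-exposure association is non-negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SummaryDataset",
    "MRResult",
    "EggerResult",
    "read_summary_tsv",
    "write_summary_tsv",
    "orient_exposure_positive",
    "DEFAULT_COLUMNS",
    "SummaryDataError",
    "FormatError",
    "ValidationError",
    "SizeError",
    "DegenerateInstrumentError",
    "SingularDesignError",
]


class SummaryDataError(Exception):
    """Base class for summary-data validation and format problems."""


class FormatError(SummaryDataError):
    """The input file does not have the required columns/layout."""


class ValidationError(SummaryDataError):
    """A value violates a dataset invariant (e.g. non-positive SE)."""


class SizeError(SummaryDataError):
    """Too few variants for the requested operation."""


class DegenerateInstrumentError(SummaryDataError):
    """An operation requiring non-zero SNP-exposure associations met a zero."""


class SingularDesignError(SummaryDataError):
    """The regression design matrix is singular (no exposure spread)."""


#: Default header names for the five required TSV columns.  There is no single
#: standard across consortium exports, so the mapping is configurable.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "snp",
    "beta_exposure": "beta_exposure",
    "se_exposure": "se_exposure",
    "beta_outcome": "beta_outcome",
    "se_outcome": "se_outcome",
}


@dataclass(frozen=True)
class SummaryDataset:
    """Per-variant two-sample summary statistics.

    Attributes
    ----------
    variant_id : array of str
        Unique variant labels.
    beta_exposure : array of float
        SNP-exposure association estimates (e.g. SD of exposure per allele).
    se_exposure : array of float
        Standard errors of the SNP-exposure associations, all > 0.
    beta_outcome : array of float
        SNP-outcome association estimates (e.g. log-odds per allele).
    se_outcome : array of float
        Standard errors of the SNP-outcome associations, all > 0.
    """

    variant_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.variant_id, dtype=object)
        arrays = {}
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValidationError(f"{name} must be one-dimensional")
            if a.shape[0] != ids.shape[0]:
                raise ValidationError(
                    f"{name} has {a.shape[0]} entries but there are "
                    f"{ids.shape[0]} variant ids"
                )
            if not np.all(np.isfinite(a)):
                bad = ids[~np.isfinite(a)][0]
                raise ValidationError(f"non-finite {name} for variant {bad!r}")
            arrays[name] = a
        # se_exposure = 0 is admitted in memory (it encodes exact NOME, the
        # SIMEX identity case); file input is stricter, see read_summary_tsv.
        if np.any(arrays["se_exposure"] < 0):
            bad = ids[arrays["se_exposure"] < 0][0]
            raise ValidationError(f"negative se_exposure for variant {bad!r}")
        if np.any(arrays["se_outcome"] <= 0):
            bad = ids[arrays["se_outcome"] <= 0][0]
            raise ValidationError(f"non-positive se_outcome for variant {bad!r}")
        if len(set(ids.tolist())) != len(ids):
            raise ValidationError("variant_id values must be unique")
        if len(ids) < 2:
            raise SizeError("a summary dataset needs at least 2 variants")
        object.__setattr__(self, "variant_id", ids)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    @property
    def L(self) -> int:
        """Number of variants."""
        return int(self.variant_id.shape[0])

    def to_frame(self, columns: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
        """Return the dataset as a DataFrame with the given header names."""
        cols = dict(DEFAULT_COLUMNS)
        if columns:
            cols.update(columns)
        return pd.DataFrame(
            {
                cols["variant_id"]: self.variant_id,
                cols["beta_exposure"]: self.beta_exposure,
                cols["se_exposure"]: self.se_exposure,
                cols["beta_outcome"]: self.beta_outcome,
                cols["se_outcome"]: self.se_outcome,
            }
        )

    def replace(self, **changes) -> "SummaryDataset":
        return dataclasses.replace(self, **changes)


def read_summary_tsv(
    path, columns: Optional[Mapping[str, str]] = None
) -> SummaryDataset:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path : path-like
        TSV file with a header row.  Required columns (by default): ``snp``,
        ``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``.
        Extra columns are ignored.
    columns : mapping, optional
        Remapping from canonical field names (``variant_id``,
        ``beta_exposure``, ...) to the header names actually used in the file.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a standard error is non-positive (the offending variant is named).
    SizeError
        If the file has fewer than 2 data rows.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing} in {path} "
            f"(found: {list(frame.columns)})"
        )
    if len(frame) < 2:
        raise SizeError(f"{path} has {len(frame)} data rows; need at least 2")
    se_x = frame[cols["se_exposure"]].to_numpy(dtype=float)
    if np.any(se_x <= 0):
        bad = frame[cols["variant_id"]].iloc[int(np.argmax(se_x <= 0))]
        raise ValidationError(f"non-positive se_exposure for variant {bad!r}")
    return SummaryDataset(
        variant_id=frame[cols["variant_id"]].astype(str).to_numpy(dtype=object),
        beta_exposure=frame[cols["beta_exposure"]].to_numpy(dtype=float),
        se_exposure=frame[cols["se_exposure"]].to_numpy(dtype=float),
        beta_outcome=frame[cols["beta_outcome"]].to_numpy(dtype=float),
        se_outcome=frame[cols["se_outcome"]].to_numpy(dtype=float),
    )


def write_summary_tsv(
    dataset: SummaryDataset, path, columns: Optional[Mapping[str, str]] = None
) -> None:
    """Write a dataset as TSV.  Floats use shortest round-tripping repr, so a
    write/read cycle reproduces every numeric field bit-exactly."""
    frame = dataset.to_frame(columns)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                "\t".join(
                    repr(float(v)) if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def orient_exposure_positive(dataset: SummaryDataset) -> SummaryDataset:
    """Recode alleles so all SNP-exposure associations are non-negative.

    For each variant with a negative SNP-exposure association, both the
    exposure and the outcome association estimates are negated (equivalent to
    swapping effect and other allele); standard errors are unchanged.
    Variants with ``beta_exposure >= 0`` are untouched, so the operation is
    idempotent, and per-variant ratio estimates are invariant under it.
    """
    flip = dataset.beta_exposure < 0
    if not np.any(flip):
        return dataset
    sign = np.where(flip, -1.0, 1.0)
    return dataset.replace(
        beta_exposure=dataset.beta_exposure * sign,
        beta_outcome=dataset.beta_outcome * sign,
    )


@dataclass(frozen=True)
class MRResult:
    """A single causal-scale estimate with t-based inference.

    ``overdispersion`` is the multiplicative residual scale used for the
    standard error: for inverse-variance-weighted fits it is the factor
    phi = max(1, sqrt(RSS_w / df)) (floored at 1, so heterogeneity can only
    inflate fixed-effect SEs); for unweighted fits it is the raw residual SD.
    """

    estimate: float
    se: float
    t_value: float
    p_value: float
    df: int
    method: str
    n_variants: int
    overdispersion: float = 1.0

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "t_value": self.t_value,
            "p_value": self.p_value,
            "df": self.df,
            "method": self.method,
            "n_variants": self.n_variants,
            "overdispersion": self.overdispersion,
        }


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger intercept/slope pair with attached diagnostics.

    The intercept estimates the average directional pleiotropic effect; the
    slope estimates the causal effect.  Both carry df = L - 2.
    ``i2_gx`` optionally attaches the instrument-strength diagnostic;
    ``adjusted`` marks SIMEX-corrected results; ``n_flipped`` records how many
    variants were recoded by the internal positive-orientation step.
    """

    intercept: MRResult
    slope: MRResult
    weighted: bool
    i2_gx: Optional[float] = None
    adjusted: bool = False
    n_flipped: int = 0
    extra: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept.to_dict(),
            "slope": self.slope.to_dict(),
            "weighted": self.weighted,
            "adjusted": self.adjusted,
            "n_flipped": self.n_flipped,
        }
        if self.i2_gx is not None:
            d["i2_gx"] = self.i2_gx
        return d
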