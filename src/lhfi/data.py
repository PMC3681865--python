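"""Domain types and I/O for benthic metric counts and abiotic covariates.

The data model mirrors a standard estuarine benthic survey design: a set of
sites, each visited in one month, with 2-3 replicate grab samples per site.
Each grab yields abundance counts of benthic organisms classified into the
five AMBI ecological groups (group 1 = pollution-sensitive ... group 5 =
first-order opportunist), plus a total organism count.  Counts need not
exhaust the total: the difference is an explicit "remainder" of organisms
not assigned to any AMBI group, which also serves as the baseline category
of the multinomial observation model.

Abiotic covariates are stored per site in their raw units; transformation
(log for depth and silt-clay) and mean-centering happen in
:func:`build_centered_design`, which records the centering constants so a
fitted model can be applied to new sites with the original constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricScheme",
    "BenthicDataset",
    "CovariateTable",
    "CenteredDesign",
    "read_counts_csv",
    "write_counts_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "build_centered_design",
    "project_distance_downstream",
]

COUNT_COLUMNS = ["site", "month", "replicate", "m1", "m2", "m3", "m4", "m5", "total"]
COVARIATE_COLUMNS = [
    "site",
    "month",
    "depth_m",
    "temp_c",
    "salinity_ppt",
    "silt_clay",
    "median_grain",
    "sorting",
    "organic_pct",
    "dd_km",
]

MONTHS = ("Sep", "Oct")


class DataFormatError(ValueError):
    """Raised when an input table is structurally malformed."""


class DataValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


@dataclass(frozen=True)
class MetricScheme:
    """Partition of metrics into a health-positive and health-negative group.

    For the AMBI default, metrics 1-2 (sensitive / indifferent taxa) form the
    "plus" group and metrics 3-5 (tolerant / opportunistic taxa) the "minus"
    group; the sign enters the linear predictor so that abundant minus-group
    taxa indicate poor health.
    """

    metric_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    group_of: Mapping[int, str] = field(
        default_factory=lambda: {1: "plus", 2: "plus", 3: "minus", 4: "minus", 5: "minus"}
    )
    sign_of: Mapping[str, int] = field(default_factory=lambda: {"plus": +1, "minus": -1})

    def __post_init__(self) -> None:
        if set(self.group_of) != set(self.metric_ids):
            raise DataValidationError("every metric must belong to exactly one group")
        if set(self.group_of.values()) - set(self.sign_of):
            raise DataValidationError("group without a sign")

    def metrics_in(self, group: str) -> tuple[int, ...]:
        return tuple(m for m in self.metric_ids if self.group_of[m] == group)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.group_of[m] for m in self.metric_ids))


AMBI_SCHEME = MetricScheme()


@dataclass
class BenthicDataset:
    """Replicate-level metric counts: one row per grab sample.

    Backed by a DataFrame with columns ``site, month, replicate, m1..m5,
    total``.  The per-row remainder (total minus the five metric counts) is
    the count of organisms not classified into any metric group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"counts table missing columns: {missing}")
        df = df[COUNT_COLUMNS].copy()
        for c in ["site", "replicate", "m1", "m2", "m3", "m4", "m5", "total"]:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
        if (df[["m1", "m2", "m3", "m4", "m5", "total"]] < 0).any().any():
            raise DataValidationError("negative counts")
        bad_month = ~df["month"].isin(MONTHS)
        if bad_month.any():
            raise DataValidationError(f"unknown month values: {df.loc[bad_month, 'month'].unique()}")
        msum = df[["m1", "m2", "m3", "m4", "m5"]].sum(axis=1)
        over = msum > df["total"]
        if over.any():
            row = df.index[over][0]
            raise DataValidationError(
                f"metric counts sum to {msum[row]} > total {df.loc[row, 'total']} "
                f"at site {df.loc[row, 'site']} replicate {df.loc[row, 'replicate']}"
            )
        df = df.sort_values(["site", "replicate"], kind="stable").reset_index(drop=True)
        self.frame = df

    @property
    def sites(self) -> np.ndarray:
        return np.unique(self.frame["site"].to_numpy())

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def counts(self) -> np.ndarray:
        """(n_records, 5) metric count matrix."""
        return self.frame[["m1", "m2", "m3", "m4", "m5"]].to_numpy()

    def totals(self) -> np.ndarray:
        return self.frame["total"].to_numpy()

    def remainders(self) -> np.ndarray:
        return self.totals() - self.counts().sum(axis=1)

    def site_index(self) -> np.ndarray:
        """Per-record index into ``self.sites`` (0-based)."""
        return np.searchsorted(self.sites, self.frame["site"].to_numpy())

    def month_of_site(self) -> np.ndarray:
        """Month label per site, in ``sites`` order."""
        first = self.frame.groupby("site", sort=True)["month"].first()
        return first.to_numpy()

    def replicates_per_site(self) -> np.ndarray:
        return self.frame.groupby("site", sort=True).size().to_numpy()


@dataclass
class CovariateTable:
    """One row of abiotic covariates per site, in raw (untransformed) units."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"covariate table missing columns: {missing}")
        df = df[COVARIATE_COLUMNS].copy()
        if len(df) == 0:
            raise DataValidationError("no sites in covariate table")
        df["site"] = pd.to_numeric(df["site"], errors="raise").astype(int)
        dup = df["site"].duplicated()
        if dup.any():
            raise DataValidationError(f"duplicate site {df.loc[dup, 'site'].iloc[0]}")
        for c in COVARIATE_COLUMNS[2:]:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        sc = df["silt_clay"]
        if ((sc <= 0) | (sc > 1)).any():
            bad = df.loc[(sc <= 0) | (sc > 1), "site"].iloc[0]
            raise DataValidationError(f"silt_clay outside (0, 1] at site {bad}")
        if (df["dd_km"] < 0).any():
            raise DataValidationError("negative distance downstream")
        df = df.sort_values("site", kind="stable").reset_index(drop=True)
        self.frame = df

    @property
    def sites(self) -> np.ndarray:
        return self.frame["site"].to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


# Named covariate terms available to the health regression.  Each maps to a
# raw column and a transform applied before centering.
_TERMS: dict[str, tuple[str, str]] = {
    "dd": ("dd_km", "identity"),
    "salinity": ("salinity_ppt", "identity"),
    "log_depth": ("depth_m", "log"),
    "log_sc": ("silt_clay", "log"),
    "temp": ("temp_c", "identity"),
    "median_grain": ("median_grain", "identity"),
    "sorting": ("sorting", "identity"),
    "organic": ("organic_pct", "log"),
}


def _is_interaction(term: str) -> bool:
    return ":" in term


@dataclass
class CenteredDesign:
    """Transformed, centered design matrix for the latent health regression.

    ``matrix`` holds one column per requested term (interactions are products
    of the centered parent columns).  ``centering_constants`` stores, per
    non-interaction term, the constant subtracted after transformation, so
    that prediction at new sites can reuse a fit's centering.
    """

    terms: tuple[str, ...]
    matrix: np.ndarray  # (n_sites, n_terms)
    centering_constants: dict[str, float]
    transform_flags: dict[str, str]
    centered_dd: np.ndarray
    centered_salinity: np.ndarray
    sites: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    def column(self, term: str) -> np.ndarray:
        return self.matrix[:, self.terms.index(term)]


def _transformed_column(cov: CovariateTable, term: str) -> np.ndarray:
    if term not in _TERMS:
        raise KeyError(f"unknown covariate term {term!r}; known: {sorted(_TERMS)}")
    col, transform = _TERMS[term]
    x = cov.column(col)
    if transform == "log":
        if (x <= 0).any():
            raise DataValidationError(f"log transform of nonpositive values in {col}")
        x = np.log(x)
    return x


def build_centered_design(
    cov: CovariateTable,
    terms: Sequence[str],
    constants: Mapping[str, float] | None = None,
) -> CenteredDesign:
    """Build the health-regression design matrix.

    Parameters
    ----------
    terms
        Ordered covariate names from ``{dd, salinity, log_depth, log_sc,
        temp, median_grain, sorting, organic}`` and interactions written
        ``"a:b"``.  An interaction column is the elementwise product of the
        two centered parent columns.
    constants
        Centering constants per non-interaction term.  When omitted, sample
        means of the transformed columns are used (and stored).
    """
    base_terms: list[str] = []
    for t in terms:
        parents = t.split(":") if _is_interaction(t) else [t]
        for p in parents:
            if p not in base_terms:
                base_terms.append(p)
    # dd and salinity are always carried (centered) for the two-level model,
    # even when not in the health regression.
    for extra in ("dd", "salinity"):
        if extra not in base_terms:
            base_terms.append(extra)

    consts: dict[str, float] = {}
    flags: dict[str, str] = {}
    centered: dict[str, np.ndarray] = {}
    for t in base_terms:
        x = _transformed_column(cov, t)
        c = float(constants[t]) if constants is not None and t in constants else float(np.mean(x))
        consts[t] = c
        flags[t] = _TERMS[t][1]
        centered[t] = x - c

    cols = []
    for t in terms:
        if _is_interaction(t):
            a, b = t.split(":")
            cols.append(centered[a] * centered[b])
        else:
            cols.append(centered[t])
    matrix = np.column_stack(cols) if cols else np.empty((cov.n_sites, 0))
    return CenteredDesign(
        terms=tuple(terms),
        matrix=matrix,
        centering_constants=consts,
        transform_flags=flags,
        centered_dd=centered["dd"],
        centered_salinity=centered["salinity"],
        sites=cov.sites.copy(),
    )


def project_distance_downstream(coords: np.ndarray) -> np.ndarray:
    """Distance downstream by perpendicular projection onto the channel axis.

    The axis runs from the first site (most upstream) to the last site (most
    downstream); each site's distance is the scalar projection of its offset
    from the first site onto the unit axis vector.  Coordinates are planar
    kilometres; the first site maps to 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_sites >= 2, 2)")
    axis = coords[-1] - coords[0]
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ValueError("degenerate axis: first and last site coincide")
    return (coords - coords[0]) @ (axis / norm)


def read_counts_csv(path: str | Path) -> BenthicDataset:
    """Read a replicate-level counts CSV (columns site,month,replicate,m1..m5,total)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty counts file") from exc
    return BenthicDataset(df)


def write_counts_csv(data: BenthicDataset, path: str | Path) -> None:
    data.frame.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> CovariateTable:
    """Read a per-site covariate CSV (one row per site)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"{path}: no sites") from exc
    return CovariateTable(df)


def write_covariates_csv(cov: CovariateTable, path: str | Path) -> None:
    cov.frame.to_csv(path, index=False)
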