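"""Two-group nonparametric inference over graph metrics.

The observed statistic is the Welch two-sample t (groups are unbalanced, 19
cases vs 52 controls, and variances need not match); the null distribution
is built by shuffling pooled group labels, with the add-one convention
p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1) so p is never zero. The
default design is 7 global indices x 4 bands = 28 tests with
Benjamini-Hochberg FDR across all 28; nodal follow-up tests (betweenness /
eccentricity per ROI) run only in bands flagged globally, with FDR across
the 84 ROIs within each metric/band family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from restnet.util import as_seed_sequence

logger = logging.getLogger(__name__)

#: The seven global graph indices, in reporting order.
GLOBAL_INDICES = (
    "swp",
    "path",
    "clustering",
    "max_bc",
    "leaf_fraction",
    "diameter",
    "avg_eccentricity",
)


@dataclass
class MetricsTable:
    """Per-subject global graph indices across bands.

    Attributes
    ----------
    values : DataFrame
        Index: subject id. Columns: MultiIndex (index_name, band_name).
    groups : Series
        Binary group label per subject (aligned with ``values``).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = self.groups[self.groups.isna()].index.tolist()
            raise ValueError(f"subjects without a group label: {missing}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing metric cells for subjects: {bad}")
        if self.groups.nunique() != 2:
            raise ValueError("exactly two groups are required")

    @property
    def group_labels(self) -> tuple:
        # stable order: first-seen label first (cases listed first by cohort
        # builders); tests are two-sided so the order only fixes the t sign
        seen = self.groups.drop_duplicates().tolist()
        return tuple(seen)


@dataclass(frozen=True)
class GroupTestResult:
    """One permutation-test comparison (global index or nodal metric)."""

    index: str
    band: str
    t_obs: float
    p: float
    q: float
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n_x: int
    n_y: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    se2 = x.var(ddof=1) / nx + y.var(ddof=1) / ny
    if se2 <= 0:
        # both groups internally constant: infinite separation unless equal
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(se2))


def _perm_abs_welch_t(pooled: np.ndarray, n_small: int, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorized |Welch t| over label permutations of a pooled sample.

    The pool is sorted and the smaller group size is always drawn first, so
    the realized null is identical whichever way the caller labelled the
    two samples (exact x <-> y exchange invariance of the p-value).
    """
    pooled = np.sort(pooled)
    n = pooled.size
    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)
    perm = pooled[idx]
    x, y = perm[:, :n_small], perm[:, n_small:]
    diff = x.mean(axis=1) - y.mean(axis=1)
    se2 = x.var(axis=1, ddof=1) / n_small + y.var(axis=1, ddof=1) / (n - n_small)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / np.sqrt(se2)
    return np.where(se2 > 0, t, np.where(diff == 0, 0.0, np.inf))


def permutation_test(
    x,
    y,
    n_perm: int = 5000,
    seed: int | None = None,
    index: str = "",
    band: str = "",
) -> GroupTestResult:
    """Two-sided label-permutation test with a Welch-t statistic.

    Parameters
    ----------
    x, y : array-like
        The two samples (each of size >= 2).
    n_perm : int
        Number of random label shuffles (default 5000).
    seed : int, optional
    index, band : str
        Carried through to the result record for reporting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if pooled.var(ddof=1) <= 0:
        warnings.warn("zero pooled variance; p set to 1", stacklevel=2)
        return GroupTestResult(
            index=index, band=band, t_obs=0.0, p=1.0, q=np.nan,
            mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
            mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
            n_x=len(x), n_y=len(y),
        )
    t_obs = _welch_t(x, y)
    rng = np.random.default_rng(seed)
    abs_t_perm = _perm_abs_welch_t(pooled, min(len(x), len(y)), n_perm, rng)
    p = (1.0 + np.count_nonzero(abs_t_perm >= abs(t_obs))) / (n_perm + 1.0)
    return GroupTestResult(
        index=index, band=band, t_obs=t_obs, p=float(p), q=np.nan,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        n_x=len(x), n_y=len(y),
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


def _attach_q(results: list[GroupTestResult]) -> list[GroupTestResult]:
    q = fdr_bh([r.p for r in results])
    return [
        GroupTestResult(**{**r.to_dict(), "q": float(qi)})
        for r, qi in zip(results, q)
    ]


def compare_global(
    table: MetricsTable, n_perm: int = 5000, seed: int | None = None
) -> list[GroupTestResult]:
    """One permutation test per global index x band; FDR across all cells.

    With the default 7 indices and 4 bands this is the 28-test design; the
    BH correction is applied jointly over all 28 p-values.
    """
    ga, gb = table.group_labels
    mask_a = (table.groups == ga).to_numpy()
    cells = list(table.values.columns)
    ss = as_seed_sequence(seed)
    children = ss.spawn(len(cells))
    results = []
    for (index_name, band_name), cs in zip(cells, children):
        col = table.values[(index_name, band_name)].to_numpy(dtype=float)
        res = permutation_test(
            col[mask_a], col[~mask_a],
            n_perm=n_perm, seed=cs, index=index_name, band=band_name,
        )
        results.append(res)
    return _attach_q(results)


#: Global index whose significance licenses each nodal follow-up family.
NODAL_GATE = {"bc": "max_bc", "eccentricity": "avg_eccentricity"}


def gated_families(
    global_results: list[GroupTestResult], alpha: float = 0.05
) -> list[tuple[str, str]]:
    """Nodal (metric, band) families licensed by the global analysis.

    Nodal betweenness is tested in bands where the global maximum
    betweenness was significant (q < alpha); nodal eccentricity where the
    global average eccentricity was.
    """
    fams = []
    for metric, gate_index in NODAL_GATE.items():
        for r in global_results:
            if r.index == gate_index and r.q < alpha:
                fams.append((metric, r.band))
    return fams


def compare_nodal(
    bc_tables: dict[str, pd.DataFrame],
    ecc_tables: dict[str, pd.DataFrame],
    groups: pd.Series,
    flagged: list[tuple[str, str]],
    n_perm: int = 5000,
    seed: int | None = None,
    global_results: list[GroupTestResult] | None = None,
    alpha: float = 0.05,
    override_gating: bool = False,
) -> list[GroupTestResult]:
    """Per-ROI follow-up permutation tests, gated on the global analysis.

    Parameters
    ----------
    bc_tables, ecc_tables : dict band -> DataFrame (subjects x ROI labels)
        Nodal betweenness and eccentricity values per band.
    groups : Series
        Group label per subject.
    flagged : list of (metric, band)
        Metric/band families to test; metric in {"bc", "eccentricity"}.
    n_perm, seed :
        As in :func:`permutation_test`.
    global_results : list of GroupTestResult, optional
        When given, each requested family must be licensed by a
        significant global max_bc / avg_eccentricity cell in that band
        (q < alpha); otherwise a gating error is raised unless
        ``override_gating`` is set.
    alpha : float
        Gating significance threshold on the global q-values.
    override_gating : bool
        Allow testing arbitrary families (exploratory use).

    Returns
    -------
    list of GroupTestResult
        One record per ROI per family; FDR applied within each
        metric/band family.
    """
    tables = {"bc": bc_tables, "eccentricity": ecc_tables}
    allowed = (
        None
        if global_results is None or override_gating
        else set(gated_families(global_results, alpha=alpha))
    )
    for metric, band in flagged:
        if metric not in tables:
            raise ValueError(f"unknown nodal metric {metric!r}")
        if band not in tables[metric]:
            raise ValueError(f"no nodal {metric} table for band {band!r}")
        if allowed is not None and (metric, band) not in allowed:
            raise ValueError(
                f"nodal {metric} in band {band!r} is not licensed by the "
                "global analysis; pass override_gating=True to test it anyway"
            )
    ss = as_seed_sequence(seed)
    out: list[GroupTestResult] = []
    for metric, band in flagged:
        df = tables[metric][band]
        g = groups.reindex(df.index)
        ga = g.iloc[0]
        mask_a = (g == ga).to_numpy()
        children = ss.spawn(df.shape[1])
        fam = []
        for roi, cs in zip(df.columns, children):
            col = df[roi].to_numpy(dtype=float)
            fam.append(
                permutation_test(
                    col[mask_a], col[~mask_a], n_perm=n_perm, seed=cs,
                    index=f"{metric}:{roi}", band=band,
                )
            )
        out.extend(_attach_q(fam))
    return out


def results_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Tidy results table (index, band, t, p, q, group means and SDs)."""
    return pd.DataFrame([r.to_dict() for r in results])
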