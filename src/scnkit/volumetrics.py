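"""Regional brain volumetrics: tables, covariate-adjusted contrasts, associations.

The analyses here operate on per-animal regional volume tables (mm^3).
Group contrasts fit, per region and per group pair, an ordinary linear
model ``volume ~ intercept + group + TBV`` where TBV (total brain volume)
is a covariate that absorbs overall brain-size differences; the reported
statistic is the t for the group indicator.  Brain-behaviour associations
regress per-animal Y-maze alternation counts (binomial) on TBV-residualized
regional volume and report the signed Wald z for the slope.  Both analyses
control the family-wise error rate with the Bonferroni-Holm step-down.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionHierarchy

__all__ = [
    "VolumeTable",
    "ContrastResult",
    "AssociationResult",
    "average_hemispheres",
    "reduce_to_rois",
    "residualize_on_tbv",
    "residualize_all",
    "glm_group_contrast",
    "glm_group_contrast_all",
    "holm_adjust",
    "associate_with_behavior",
]

_HEMI_RE = re.compile(r"^(?P<base>.+) \((?P<side>left|right)\)$")

_RESERVED = ("group", "tbv")


@dataclass
class VolumeTable:
    """Animals x regions volume matrix with group labels and total brain volume.

    ``frame`` is indexed by animal id and holds a ``group`` column, a ``tbv``
    column (total brain volume, mm^3) and one column per region (mm^3).
    Fine-region columns may carry a hemisphere tag in the column name, e.g.
    ``"orbital area (left)"``; untagged columns are taken as bilateral.
    ``group_order`` fixes the ordered set of admissible age-group labels.
    """

    frame: pd.DataFrame
    group_order: tuple[str, ...] = ("young", "middle", "old")

    def __post_init__(self) -> None:
        self.group_order = tuple(self.group_order)
        f = self.frame
        for col in _RESERVED:
            if col not in f.columns:
                raise ValueError(f"volume table lacks required column {col!r}")
        if not self.regions:
            raise ValueError("volume table has no region columns")
        vols = f[list(self.regions)]
        if vols.isna().any().any() or f["tbv"].isna().any():
            raise ValueError("volume table contains missing cells")
        if (vols.to_numpy(float) <= 0).any():
            bad = vols.columns[(vols <= 0).any()].tolist()
            raise ValueError(f"non-positive volumes in regions: {bad}")
        if (f["tbv"].to_numpy(float) < vols.to_numpy(float).max(axis=1)).any():
            raise ValueError("tbv smaller than a single-region volume")
        unknown = set(f["group"]) - set(self.group_order)
        if unknown:
            raise ValueError(f"group labels outside the configured set: {sorted(unknown)}")
        if f.index.has_duplicates:
            raise ValueError("duplicate animal ids")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c not in _RESERVED)

    @property
    def animals(self) -> tuple[str, ...]:
        return tuple(self.frame.index.astype(str))

    def groups_present(self) -> tuple[str, ...]:
        present = set(self.frame["group"])
        return tuple(g for g in self.group_order if g in present)

    def subset(self, groups: Iterable[str]) -> "VolumeTable":
        groups = tuple(groups)
        mask = self.frame["group"].isin(groups)
        return VolumeTable(self.frame.loc[mask].copy(), self.group_order)

    def volumes(self, regions: Sequence[str] | None = None) -> np.ndarray:
        cols = list(regions) if regions is not None else list(self.regions)
        return self.frame[cols].to_numpy(float)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "animal_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, group_order: Sequence[str] = ("young", "middle", "old")) -> "VolumeTable":
        frame = pd.read_csv(path, index_col="animal_id", float_precision="round_trip")
        frame.index = frame.index.astype(str)
        return cls(frame, tuple(group_order))


@dataclass(frozen=True)
class ContrastResult:
    """Covariate-adjusted pairwise group contrast for one region.

    ``t`` is the statistic for the group indicator (coded so that negative t
    means the second — older — group is smaller); ``p_raw`` is two-tailed on
    n-3 degrees of freedom; ``p_adj`` is Holm-adjusted within the declared
    family (NaN until a family correction is applied).
    """

    region: str
    comparison: tuple[str, str]
    t: float
    p_raw: float
    p_adj: float = float("nan")
    df: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.p_adj) and self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass(frozen=True)
class AssociationResult:
    """Sample-wide volume–behaviour association for one region.

    ``stat`` is the signed Wald z for the slope of alternation odds on
    TBV-residualized volume (its sign equals the slope's sign).
    """

    region: str
    stat: float
    p_raw: float
    p_adj: float = float("nan")
    family: str = ""
    slope: float = float("nan")
    converged: bool = True


def average_hemispheres(table: VolumeTable) -> VolumeTable:
    """Average left/right tagged region columns into bilateral columns.

    Untagged columns pass through unchanged.  A region present with only
    one hemisphere tag is an error (all orphans are listed).
    """
    frame = table.frame
    sides: dict[str, dict[str, str]] = {}
    plain: list[str] = []
    for col in table.regions:
        m = _HEMI_RE.match(col)
        if m:
            sides.setdefault(m["base"], {})[m["side"]] = col
        else:
            plain.append(col)
    orphans = sorted(b for b, s in sides.items() if len(s) != 2)
    if orphans:
        raise ValueError(f"regions present in only one hemisphere: {orphans}")
    cols = {col: frame[col] for col in plain}
    for base, s in sides.items():
        cols[base] = (frame[s["left"]].astype(float) + frame[s["right"]].astype(float)) / 2.0
    out = pd.concat([frame[["group", "tbv"]], pd.DataFrame(cols)], axis=1)
    return VolumeTable(out, table.group_order)


def reduce_to_rois(table: VolumeTable, hierarchy: RegionHierarchy) -> VolumeTable:
    """Sum fine-region volumes into the hierarchy's ROIs.

    The mapping must be total over the table's region columns; total
    measured volume is conserved.
    """
    unmapped = [r for r in table.regions if r not in hierarchy.mapping]
    if unmapped:
        raise ValueError(f"fine regions missing from hierarchy: {unmapped}")
    out = table.frame[["group", "tbv"]].copy()
    for roi in hierarchy.rois:
        members = [f for f in hierarchy.members(roi) if f in table.regions]
        if members:
            out[roi] = table.frame[members].to_numpy(float).sum(axis=1)
    return VolumeTable(out, table.group_order)


def _tbv_design(tbv: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(tbv), tbv])


def residualize_on_tbv(table: VolumeTable, region: str) -> pd.Series:
    """OLS residuals of one region's volume on intercept + total brain volume."""
    return residualize_all(table, [region])[region]


def residualize_all(table: VolumeTable, regions: Sequence[str] | None = None) -> pd.DataFrame:
    """TBV-residualize every requested region over the table's full sample.

    Residuals sum to zero and are uncorrelated with TBV by construction.
    """
    if len(table.frame) < 3:
        raise ValueError("need at least 3 animals to residualize")
    tbv = table.frame["tbv"].to_numpy(float)
    if np.ptp(tbv) == 0:
        raise ValueError("total brain volume is constant: rank-deficient design")
    X = _tbv_design(tbv)
    Y = table.volumes(regions)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    cols = list(regions) if regions is not None else list(table.regions)
    return pd.DataFrame(resid, index=table.frame.index, columns=cols)


def _contrast_core(
    y: np.ndarray, older: np.ndarray, tbv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """t statistics and two-tailed p for the group coefficient, all regions.

    Closed-form multi-response OLS of y ~ 1 + older + tbv.  ``y`` is
    (n, n_regions); ``older`` is the 0/1 indicator of the second group.
    """
    n = len(older)
    X = np.column_stack([np.ones(n), older.astype(float), tbv])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design (tbv constant within the pair?)")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - 3
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    # exact fit (zero residual variance): t is 0 when the group coefficient
    # itself vanishes, infinite otherwise
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    scale = np.sqrt(np.maximum(tss, 1e-300))
    exact = rss <= 1e-20 * np.maximum(tss, 1e-300) + 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            exact,
            np.where(np.abs(beta[1]) <= 1e-10 * scale, 0.0, np.inf * np.sign(beta[1])),
            beta[1] / se,
        )
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, df


def glm_group_contrast(
    table: VolumeTable, region: str, pair: tuple[str, str]
) -> ContrastResult:
    """Pairwise covariate-adjusted group contrast for one region.

    Fits ``volume ~ intercept + older + tbv`` on the two groups' animals
    only, where ``older`` indicates the second group of ``pair`` (expected
    to be the older one), so negative t means a period-specific decrease.
    """
    res = glm_group_contrast_all(table, pair, regions=[region])
    return res[0]


def glm_group_contrast_all(
    table: VolumeTable, pair: tuple[str, str], regions: Sequence[str] | None = None
) -> list[ContrastResult]:
    """Vectorized pairwise contrasts for many regions at once."""
    g1, g2 = pair
    sub = table.subset([g1, g2])
    counts = sub.frame["group"].value_counts()
    for g in pair:
        if counts.get(g, 0) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 animals")
    older = (sub.frame["group"] == g2).to_numpy()
    tbv = sub.frame["tbv"].to_numpy(float)
    cols = list(regions) if regions is not None else list(sub.regions)
    y = sub.volumes(cols)
    t, p, df = _contrast_core(y, older, tbv)
    return [
        ContrastResult(region=c, comparison=(g1, g2), t=float(ti), p_raw=float(pi), df=df)
        for c, ti, pi in zip(cols, t, p)
    ]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a running
    maximum and cap at 1.  Adjusted values are >= raw and order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d vector of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _adjust_contrasts(results: Sequence[ContrastResult]) -> list[ContrastResult]:
    adj = holm_adjust([r.p_raw for r in results])
    return [replace(r, p_adj=float(a)) for r, a in zip(results, adj)]


def contrast_family(
    table: VolumeTable,
    pair: tuple[str, str],
    regions: Sequence[str] | None = None,
) -> list[ContrastResult]:
    """Contrasts for a region family with Holm correction over that family."""
    return _adjust_contrasts(glm_group_contrast_all(table, pair, regions))


def associate_with_behavior(
    table: VolumeTable,
    behavior: Mapping[str, tuple[int, int]],
    regions: Sequence[str] | None = None,
    family: str = "brain_wide",
    dispersion: bool = False,
) -> list[AssociationResult]:
    """Sample-wide binomial regression of alternation on residualized volume.

    For each region, fits (successes out of scorable trials) ~ intercept +
    TBV-residualized volume over all animals pooled across groups, and
    reports the signed Wald z for the slope with a two-tailed asymptotic p.
    Holm correction is applied across the requested region family.  With
    ``dispersion=True`` standard errors are inflated by the Pearson-X^2
    overdispersion estimate (quasi-binomial).

    Degenerate outcomes (all animals all-successes or all-failures, or a
    non-converged fit) are flagged ``converged=False`` with NaN p rather
    than a fabricated value; non-converged regions keep NaN adjusted p and
    do not count toward the Holm family.
    """
    import statsmodels.api as sm

    cols = list(regions) if regions is not None else list(table.regions)
    resid = residualize_all(table, cols)
    succ = np.array([behavior[a][0] for a in table.animals], dtype=float)
    tot = np.array([behavior[a][1] for a in table.animals], dtype=float)
    if (tot < 1).any():
        raise ValueError("every animal needs at least one scorable trial")
    endog = np.column_stack([succ, tot - succ])

    results: list[AssociationResult] = []
    for region in cols:
        x = resid[region].to_numpy()
        if succ.sum() == 0 or (tot - succ).sum() == 0:
            results.append(
                AssociationResult(region=region, stat=float("nan"), p_raw=float("nan"),
                                  family=family, converged=False)
            )
            continue
        X = sm.add_constant(x)
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                scale = "X2" if dispersion else None
                fit = model.fit(scale=scale)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            converged = False
            fit = None
        if fit is None or not converged or not np.isfinite(fit.bse[1]) or fit.bse[1] == 0:
            results.append(
                AssociationResult(region=region, stat=float("nan"), p_raw=float("nan"),
                                  family=family, converged=False)
            )
            continue
        z = float(fit.params[1] / fit.bse[1])
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            AssociationResult(region=region, stat=z, p_raw=p, family=family,
                              slope=float(fit.params[1]), converged=True)
        )

    ok = [i for i, r in enumerate(results) if r.converged]
    if ok:
        adj = holm_adjust([results[i].p_raw for i in ok])
        for i, a in zip(ok, adj):
            results[i] = replace(results[i], p_adj=float(a))
    return results


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region for r in results],
            "comparison": ["{} vs {}".format(*r.comparison) for r in results],
            "t": [r.t for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region for r in results],
            "wald_z": [r.stat for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "family": [r.family for r in results],
            "converged": [r.converged for r in results],
        }
    )
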