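"""Voxel-wise between-group inference on standardized ALFF maps.

Provides pooled-variance t-maps, suprathreshold cluster extraction,
cluster-level family-wise error control by permutation of group labels
(max-cluster-size null), and covariate-adjusted models: a voxel-wise image
covariate (grey-matter probability) or a scalar covariate (e.g. total
intracranial volume).

The cluster-level correction is permutational rather than random-field
based: exact under exchangeability, with the "add-one" p estimator
(1 + #{null >= observed}) / (1 + B) so corrected p is never zero.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import BrainMask, InputError, ScalarMap

__all__ = [
    "GroupDesign",
    "InferenceConfig",
    "two_sample_tmap",
    "t_test_from_summary",
    "chi_square_2x2",
    "critical_t",
    "extract_clusters",
    "permutation_cluster_fwe",
    "ancova_image_covariate",
    "ancova_scalar_covariate",
]

logger = logging.getLogger(__name__)

PATIENT = "patient"
CONTROL = "control"


@dataclass
class GroupDesign:
    """Subject ids, group labels, and optional covariates.

    ``scalar_covariates`` maps a name to one value per subject;
    ``image_covariates`` is one ScalarMap per subject on the analysis grid.
    """

    subject_ids: Sequence[str]
    groups: Sequence[str]  # PATIENT / CONTROL per subject
    scalar_covariates: dict = field(default_factory=dict)
    image_covariates: Optional[Sequence[ScalarMap]] = None

    def __post_init__(self) -> None:
        self.groups = list(self.groups)
        self.subject_ids = list(self.subject_ids)
        if len(self.groups) != len(self.subject_ids):
            raise InputError("subject_ids and groups length mismatch")
        labels = set(self.groups)
        if not labels <= {PATIENT, CONTROL}:
            raise InputError(f"unknown group labels: {labels - {PATIENT, CONTROL}}")
        counts = [self.groups.count(g) for g in (PATIENT, CONTROL)]
        if min(counts) < 2:
            raise InputError(f"need >= 2 subjects per group, got {counts}")

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def is_patient(self) -> np.ndarray:
        return np.array([g == PATIENT for g in self.groups])


@dataclass(frozen=True)
class InferenceConfig:
    cluster_forming_t: float = 3.32
    cluster_alpha: float = 0.05
    n_permutations: int = 5000
    connectivity: int = 18
    tail: str = "both"  # positive | negative | both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_forming_t <= 0:
            raise InputError("cluster_forming_t must be > 0")
        if not 0 < self.cluster_alpha < 1:
            raise InputError("cluster_alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise InputError("n_permutations must be >= 100")
        if self.connectivity not in (6, 18, 26):
            raise InputError("connectivity must be 6, 18 or 26")
        if self.tail not in ("positive", "negative", "both"):
            raise InputError("tail must be positive, negative or both")


# ---------------------------------------------------------------------------
# basic statistics

def _stack(maps: Sequence[ScalarMap]) -> np.ndarray:
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise InputError(f"maps on different grids: {shapes}")
    return np.stack([m.data for m in maps], axis=0)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (a minus b) along axis 0.

    Zero-variance positions yield t = 0.
    """
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0), 0.0)
    return t


def two_sample_tmap(
    group_a: Sequence[ScalarMap],
    group_b: Sequence[ScalarMap],
    mask: BrainMask,
) -> ScalarMap:
    """Per-voxel pooled-variance two-sample t-map (A minus B).

    df = nA + nB - 2 is stored on the returned map.  Zero-variance voxels
    get t = 0 and their count is logged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("each group needs >= 2 maps")
    a = _stack(list(group_a) + list(group_b))
    if a.shape[1:] != mask.shape:
        raise InputError(f"map grid {a.shape[1:]} != mask grid {mask.shape}")
    na = len(group_a)
    da = a[:na][:, mask.data]
    db = a[na:][:, mask.data]
    t_vals = _pooled_t(da, db)
    n_zero = int(np.sum(t_vals == 0))
    if n_zero:
        logger.info("two_sample_tmap: %d in-mask voxels with t=0", n_zero)
    out = np.zeros(mask.shape)
    out[mask.data] = t_vals
    return ScalarMap(out, mask.affine, kind="tstat", df=na + len(group_b) - 2)


def t_test_from_summary(m1, sd1, n1, m2, sd2, n2):
    """Pooled two-sample t-test from summary statistics.

    Returns ``(t, two_tailed_p)`` with df = n1 + n2 - 2.
    """
    if sd1 < 0 or sd2 < 0:
        raise InputError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise InputError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return (0.0, 1.0) if m1 == m2 else (np.inf * np.sign(m1 - m2), 0.0)
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]].

    Returns ``(statistic, two_tailed_p)``.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise InputError("counts must be >= 0")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) == 0:
        raise InputError("zero margin in 2x2 table")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = stats.chi2.sf(stat, df=1)
    return float(stat), float(p)


def critical_t(alpha: float, df: int, tails: str = "one") -> float:
    """Upper quantile of Student's t: the cluster-forming threshold for a
    voxel-wise alpha."""
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if df < 1:
        raise InputError("df must be >= 1")
    if tails not in ("one", "two"):
        raise InputError("tails must be 'one' or 'two'")
    a = alpha if tails == "one" else alpha / 2.0
    return float(stats.t.isf(a, df))


# ---------------------------------------------------------------------------
# clusters

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def _label_clusters(binary: np.ndarray, connectivity: int):
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    return labels, n


CLUSTER_COLUMNS = [
    "cluster_id", "sign", "n_voxels", "peak_t",
    "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "p_corrected",
]


def _empty_cluster_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CLUSTER_COLUMNS)


def extract_clusters(
    tmap: ScalarMap,
    threshold: float,
    connectivity: int = 18,
    tail: str = "both",
) -> pd.DataFrame:
    """Connected components of the suprathreshold t-map.

    Positive clusters are components of {t > threshold}; negative clusters
    (when the tail permits) of {t < -threshold}.  The peak is the voxel of
    maximum |t|; its world coordinate comes from the map affine.  Returns a
    table with one row per cluster (``p_corrected`` left NaN here).
    """
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    if tail not in ("positive", "negative", "both"):
        raise InputError("invalid tail")
    rows = []
    signs = []
    if tail in ("positive", "both"):
        signs.append(+1)
    if tail in ("negative", "both"):
        signs.append(-1)
    cid = 0
    for sign in signs:
        binary = (sign * tmap.data) > threshold
        labels, n = _label_clusters(binary, connectivity)
        for lab in range(1, n + 1):
            idx = np.nonzero(labels == lab)
            t_here = tmap.data[idx]
            peak_pos = int(np.argmax(np.abs(t_here)))
            ijk = (idx[0][peak_pos], idx[1][peak_pos], idx[2][peak_pos])
            world = tmap.affine @ np.array([*ijk, 1.0])
            cid += 1
            rows.append({
                "cluster_id": cid,
                "sign": sign,
                "n_voxels": int(t_here.size),
                "peak_t": float(t_here[peak_pos]),
                "peak_i": int(ijk[0]), "peak_j": int(ijk[1]), "peak_k": int(ijk[2]),
                "peak_x_mm": float(world[0]),
                "peak_y_mm": float(world[1]),
                "peak_z_mm": float(world[2]),
                "p_corrected": np.nan,
            })
    if not rows:
        return _empty_cluster_table()
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return table.sort_values("n_voxels", ascending=False, ignore_index=True)


def _max_cluster_size(t_flat, mask, threshold, connectivity, signs) -> int:
    """Largest suprathreshold cluster over the requested tails."""
    vol = np.zeros(mask.shape)
    vol[mask.data] = t_flat
    best = 0
    for sign in signs:
        labels, n = _label_clusters((sign * vol) > threshold, connectivity)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def permutation_cluster_fwe(
    maps: Sequence[ScalarMap],
    design: GroupDesign,
    mask: BrainMask,
    config: InferenceConfig = InferenceConfig(),
) -> pd.DataFrame:
    """Cluster-level FWE-corrected group comparison by label permutation.

    Observed clusters (patient minus control, at ``cluster_forming_t``) are
    scored against the permutation null distribution of the maximum cluster
    size.  When the number of distinct label arrangements is at most
    ``n_permutations`` the null is enumerated exhaustively (the observed
    arrangement included); otherwise ``n_permutations`` random relabelings
    are drawn and the add-one estimator (1 + #{>=}) / (1 + B) is used.
    Deterministic given ``config.seed``.
    """
    if len(maps) != design.n:
        raise InputError(f"{len(maps)} maps for {design.n} design rows")
    data = _stack(maps)
    if data.shape[1:] != mask.shape:
        raise InputError("map grid != mask grid")
    d = data[:, mask.data]  # (n, V)
    is_pat = design.is_patient
    n_pat = int(is_pat.sum())
    n = design.n

    signs = {"positive": (+1,), "negative": (-1,), "both": (+1, -1)}[config.tail]
    thr = config.cluster_forming_t
    conn = config.connectivity

    t_obs = _pooled_t(d[is_pat], d[~is_pat])
    tvol = np.zeros(mask.shape)
    tvol[mask.data] = t_obs
    tmap = ScalarMap(tvol, mask.affine, kind="tstat", df=n - 2)
    table = extract_clusters(tmap, thr, conn, config.tail)

    n_arrangements = comb(n, n_pat)
    if n_arrangements <= config.n_permutations:
        null_max = np.empty(n_arrangements, dtype=int)
        for i, combo in enumerate(itertools.combinations(range(n), n_pat)):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t_perm = _pooled_t(d[sel], d[~sel])
            null_max[i] = _max_cluster_size(t_perm, mask, thr, conn, signs)
        denom = n_arrangements
        add_one = 0
    else:
        rng = np.random.default_rng(config.seed)
        b = config.n_permutations
        null_max = np.empty(b, dtype=int)
        for i in range(b):
            sel = np.zeros(n, dtype=bool)
            sel[rng.choice(n, size=n_pat, replace=False)] = True
            t_perm = _pooled_t(d[sel], d[~sel])
            null_max[i] = _max_cluster_size(t_perm, mask, thr, conn, signs)
        denom = b + 1
        add_one = 1

    if len(table):
        sizes = table["n_voxels"].to_numpy()
        counts = (null_max[None, :] >= sizes[:, None]).sum(axis=1)
        table["p_corrected"] = (add_one + counts) / denom
    return table


# ---------------------------------------------------------------------------
# covariate-adjusted models

def ancova_image_covariate(
    maps: Sequence[ScalarMap],
    design: GroupDesign,
    mask: BrainMask,
) -> ScalarMap:
    """Group t-map adjusted for a per-voxel image covariate.

    Per voxel, least-squares fit of the response on {intercept, group
    indicator, that voxel's covariate value}; returns the t statistic for
    the group coefficient with df = n - 3.  A covariate column that is
    constant across subjects at a voxel carries no information and is
    dropped there (df = n - 2, matching the plain two-sample model);
    otherwise rank-deficient voxels yield t = 0 and are counted in the log.
    """
    if design.image_covariates is None:
        raise InputError("design has no image covariates")
    if len(design.image_covariates) != design.n:
        raise InputError("need one image covariate per subject")
    data = _stack(maps)
    cov = _stack(design.image_covariates)
    if data.shape[1:] != mask.shape or cov.shape[1:] != mask.shape:
        raise InputError("grid mismatch between maps, covariates and mask")

    y = data[:, mask.data]          # (n, V)
    g = cov[:, mask.data]           # (n, V)
    n, n_vox = y.shape
    grp = design.is_patient.astype(float)

    # full model per voxel: X_v = [1, group, g_v]
    x_const = np.stack([np.ones(n), grp], axis=1)  # (n, 2)
    t_out = np.zeros(n_vox)
    const_cov = np.ptp(g, axis=0) < 1e-12
    n_rank_def = 0

    # voxels with informative covariate: batched 3-column solve
    idx = np.nonzero(~const_cov)[0]
    if idx.size:
        gv = g[:, idx]                                    # (n, m)
        x3 = np.broadcast_to(x_const[None], (idx.size, n, 2)).copy()
        x = np.concatenate([x3, gv.T[:, :, None]], axis=2)  # (m, n, 3)
        yv = y[:, idx].T[:, :, None]                       # (m, n, 1)
        xtx = np.einsum("mnp,mnq->mpq", x, x)
        xty = np.einsum("mnp,mnq->mpq", x, yv)
        det = np.linalg.det(xtx)
        ok = np.abs(det) > 1e-10 * np.abs(xtx[:, 0, 0]) ** 3
        n_rank_def += int((~ok).sum())
        if ok.any():
            xtx_ok = xtx[ok]
            beta = np.linalg.solve(xtx_ok, xty[ok])        # (m_ok, 3, 1)
            resid = yv[ok] - x[ok] @ beta
            rss = np.einsum("mnq,mnq->m", resid, resid)
            df = n - 3
            sigma2 = rss / df
            inv = np.linalg.inv(xtx_ok)
            se = np.sqrt(np.maximum(sigma2 * inv[:, 1, 1], 0.0))
            tv = np.zeros(ok.sum())
            good = se > 1e-12
            tv[good] = beta[good, 1, 0] / se[good]
            t_full = np.zeros(idx.size)
            t_full[ok] = tv
            t_out[idx] = t_full

    # constant-covariate voxels: reduce to the plain two-sample model
    idx_c = np.nonzero(const_cov)[0]
    if idx_c.size:
        is_pat = design.is_patient
        t_out[idx_c] = _pooled_t(y[np.ix_(is_pat, idx_c)], y[np.ix_(~is_pat, idx_c)])

    if n_rank_def:
        logger.info("ancova_image_covariate: %d rank-deficient voxels set to t=0",
                    n_rank_def)
    out = np.zeros(mask.shape)
    out[mask.data] = t_out
    return ScalarMap(out, mask.affine, kind="tstat", df=design.n - 3)


def ancova_scalar_covariate(
    maps: Sequence[ScalarMap],
    design: GroupDesign,
    covariate_name: str,
    mask: BrainMask,
) -> ScalarMap:
    """Group t-map adjusted for a scalar per-subject covariate.

    Per voxel fit of the response on {intercept, group, covariate}; the t
    for the group coefficient has df = n - 3.  A constant covariate is
    collinear with the intercept and is dropped with a warning (df = n - 2).
    """
    if covariate_name not in design.scalar_covariates:
        raise InputError(f"covariate {covariate_name!r} not in design")
    c = np.asarray(design.scalar_covariates[covariate_name], dtype=float)
    if c.shape != (design.n,):
        raise InputError("covariate length != number of subjects")
    data = _stack(maps)
    if data.shape[1:] != mask.shape:
        raise InputError("map grid != mask grid")
    y = data[:, mask.data]
    n = design.n
    grp = design.is_patient.astype(float)

    if np.ptp(c) < 1e-12:
        logger.warning(
            "ancova_scalar_covariate: %r constant; dropped (df = n - 2)",
            covariate_name,
        )
        x = np.stack([np.ones(n), grp], axis=1)
        df = n - 2
    else:
        x = np.stack([np.ones(n), grp, c], axis=1)
        df = n - 3

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)            # (p, V)
    resid = y - x @ beta
    rss = (resid * resid).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    t = np.where(se > 1e-12, beta[1] / np.where(se > 1e-12, se, 1.0), 0.0)
    out = np.zeros(mask.shape)
    out[mask.data] = t
    return ScalarMap(out, mask.affine, kind="tstat", df=df)
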