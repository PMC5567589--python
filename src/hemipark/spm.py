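"""Voxel-wise statistics, TFCE enhancement and max-statistic permutation FWE.

The inference chain is the standard nonparametric SPM recipe for small
cohorts: a voxel-wise statistic (pooled-variance two-sample t between
groups, or Pearson r against a per-subject covariate), threshold-free
cluster enhancement (TFCE), and family-wise-error correction by comparing
each voxel's enhanced value against the permutation distribution of the
image-wide maximum.

TFCE integrates cluster extent and height over all thresholds:

    TFCE(p) = sum_{h = dh, 2dh, ..., h_max}  e_h(p)^E * h^H * dh

where ``e_h(p)`` is the voxel count of the connected component containing
``p`` after thresholding at ``h``, and ``dh = h_max / n_steps``.  Positive
and negative parts of the statistic map are enhanced separately and by
default tested against their own signed null maxima (a two-sided
``max(|.|)`` variant is available).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import Image3D
from .image_prep import SUVRImage

__all__ = [
    "StatMap",
    "TFCEResult",
    "PermutationInference",
    "ClusterVOI",
    "twosample_tmap",
    "correlation_rmap",
    "tfce_enhance",
    "permutation_inference",
    "threshold_map",
    "clusters_to_vois",
    "connectivity_structure",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class StatMap:
    image: Image3D  # statistic per voxel, 0 outside mask
    kind: str  # "t" | "r"
    mask: np.ndarray
    df: int | None = None  # for t maps
    n: int | None = None  # subjects, for r maps


@dataclass
class TFCEResult:
    enhanced_pos: Image3D
    enhanced_neg: Image3D  # enhancement of the negated negative part, >= 0
    E: float
    H: float
    n_steps: int
    connectivity: int

    @property
    def combined(self) -> np.ndarray:
        """Two-sided enhanced map (parts have disjoint support)."""
        return self.enhanced_pos.values + self.enhanced_neg.values


@dataclass
class PermutationInference:
    statmap: StatMap
    observed: TFCEResult
    corrected_p: Image3D  # side-matched corrected p (1 outside mask)
    corrected_p_pos: Image3D
    corrected_p_neg: Image3D
    null_max_pos: np.ndarray
    null_max_neg: np.ndarray
    n_effective: int
    scheme: str  # "exhaustive" | "monte_carlo"
    seed: int | None
    two_sided: bool
    alpha_levels: tuple[float, ...]


@dataclass
class ClusterVOI:
    name: str
    sign: int
    size: int
    peak_stat: float
    centroid_ijk: tuple[float, float, float]
    indices: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.indices] = True
        return m


# ---------------------------------------------------------------------------
# voxel-wise statistics


def _stack(images) -> tuple[np.ndarray, Image3D]:
    imgs = []
    for im in images:
        if isinstance(im, SUVRImage):
            im = im.image
        imgs.append(im)
    first = imgs[0]
    for im in imgs[1:]:
        first.require_same_grid(im)
    data = np.stack([np.asarray(im.values, dtype=np.float64) for im in imgs])
    return data, first


def _full_mask(shape) -> np.ndarray:
    return np.ones(shape, dtype=bool)


def _group_t_flat(X: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t along axis 0 of flattened data."""
    A, B = X[is_a], X[~is_a]
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def _corr_r_flat(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X against covariate c."""
    cc = c - c.mean()
    Xc = X - X.mean(axis=0)
    num = cc @ Xc
    den = np.sqrt((cc**2).sum() * (Xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.clip(np.where(den > 0, r, 0.0), -1.0, 1.0)


def twosample_tmap(images_a, images_b, mask: np.ndarray | None = None) -> StatMap:
    """Voxel-wise pooled-variance two-sample t map (group A minus group B)."""
    if len(images_a) < 2 or len(images_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    data, template = _stack(list(images_a) + list(images_b))
    if mask is None:
        mask = _full_mask(template.shape)
    mask = np.asarray(mask, dtype=bool)
    X = data[:, mask]
    is_a = np.zeros(data.shape[0], dtype=bool)
    is_a[: len(images_a)] = True
    t = _group_t_flat(X, is_a)
    if np.any(t == 0):
        degenerate = np.sum((X.var(axis=0) == 0))
        if degenerate:
            warnings.warn(
                f"{degenerate} voxel(s) with zero pooled variance set to t=0",
                RuntimeWarning,
                stacklevel=2,
            )
    vol = np.zeros(template.shape)
    vol[mask] = t
    return StatMap(
        template.with_values(vol),
        kind="t",
        mask=mask,
        df=len(images_a) + len(images_b) - 2,
    )


def correlation_rmap(images, covariate_values, mask: np.ndarray | None = None) -> StatMap:
    """Voxel-wise Pearson correlation of image intensity with a covariate."""
    cov = np.asarray(covariate_values, dtype=np.float64)
    if cov.ndim != 1 or len(images) != cov.size:
        raise ValueError("one covariate value per image is required")
    if cov.size < 4:
        raise ValueError("correlation map requires n >= 4 subjects")
    if np.isclose(cov.std(), 0.0):
        raise ValueError("covariate is constant; correlation undefined")
    data, template = _stack(images)
    if mask is None:
        mask = _full_mask(template.shape)
    mask = np.asarray(mask, dtype=bool)
    r = _corr_r_flat(data[:, mask], cov)
    vol = np.zeros(template.shape)
    vol[mask] = r
    return StatMap(template.with_values(vol), kind="r", mask=mask, n=cov.size)


# ---------------------------------------------------------------------------
# TFCE


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Neighbour index offsets for 6/18/26-connectivity in 3D."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    deltas = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                deltas.append((dx, dy, dz))
    return np.asarray(deltas, dtype=np.int64)


@njit(cache=False)
def _tfce_accumulate(a, nx, ny, nz, deltas, E, H, dh, n_steps, out):  # pragma: no cover
    """Threshold ladder with per-threshold flood-fill component labelling.

    ``a`` is the flattened non-negative part of the statistic map; ``out``
    accumulates size^E * h^H * dh for every suprathreshold voxel.
    """
    V = a.size
    visited = np.full(V, 0, np.int64)
    stack = np.empty(V, np.int64)
    members = np.empty(V, np.int64)
    nd = deltas.shape[0]
    nyz = ny * nz
    for k in range(1, n_steps + 1):
        h = k * dh
        hterm = (h**H) * dh
        for v0 in range(V):
            if a[v0] >= h and visited[v0] != k:
                visited[v0] = k
                stack[0] = v0
                sp = 1
                size = 0
                while sp > 0:
                    sp -= 1
                    v = stack[sp]
                    members[size] = v
                    size += 1
                    x = v // nyz
                    rem = v - x * nyz
                    y = rem // nz
                    z = rem - y * nz
                    for d in range(nd):
                        xx = x + deltas[d, 0]
                        if xx < 0 or xx >= nx:
                            continue
                        yy = y + deltas[d, 1]
                        if yy < 0 or yy >= ny:
                            continue
                        zz = z + deltas[d, 2]
                        if zz < 0 or zz >= nz:
                            continue
                        w = (xx * ny + yy) * nz + zz
                        if a[w] >= h and visited[w] != k:
                            visited[w] = k
                            stack[sp] = w
                            sp += 1
                c = (size * 1.0) ** E * hterm
                for m in range(size):
                    out[members[m]] += c
    return out


def _tfce_part(part: np.ndarray, E, H, n_steps, deltas) -> np.ndarray:
    out = np.zeros(part.size, dtype=np.float64)
    hmax = float(part.max())
    if hmax <= 0:
        return out.reshape(part.shape)
    dh = hmax / n_steps
    nx, ny, nz = part.shape
    _tfce_accumulate(
        np.ascontiguousarray(part.ravel()),
        nx,
        ny,
        nz,
        deltas,
        float(E),
        float(H),
        dh,
        int(n_steps),
        out,
    )
    return out.reshape(part.shape)


def tfce_enhance(
    statmap: StatMap | Image3D,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    connectivity: int = 6,
) -> TFCEResult:
    """Enhance a statistic map; positive and negative parts separately.

    ``dh`` is computed per part as that part's maximum divided by
    ``n_steps``, so each sign is integrated over its own height range.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    img = statmap.image if isinstance(statmap, StatMap) else statmap
    vals = np.asarray(img.values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("statistic map contains non-finite values")
    deltas = connectivity_structure(connectivity)
    pos = _tfce_part(np.maximum(vals, 0.0), E, H, n_steps, deltas)
    neg = _tfce_part(np.maximum(-vals, 0.0), E, H, n_steps, deltas)
    return TFCEResult(
        enhanced_pos=img.with_values(pos),
        enhanced_neg=img.with_values(neg),
        E=E,
        H=H,
        n_steps=n_steps,
        connectivity=connectivity,
    )


# ---------------------------------------------------------------------------
# permutation inference


def _group_relabelings(n: int, n_a: int, n_perm: int, max_exhaustive: int, rng):
    """Yield boolean group-A membership vectors; exhaustive when feasible."""
    total = math.comb(n, n_a)
    if total <= max_exhaustive:
        def gen():
            for combo in itertools.combinations(range(n), n_a):
                is_a = np.zeros(n, dtype=bool)
                is_a[list(combo)] = True
                yield is_a

        return gen(), total, "exhaustive"

    def gen_mc():
        for _ in range(n_perm):
            idx = rng.choice(n, size=n_a, replace=False)
            is_a = np.zeros(n, dtype=bool)
            is_a[idx] = True
            yield is_a

    return gen_mc(), n_perm, "monte_carlo"


def _covariate_permutations(cov: np.ndarray, n_perm: int, max_exhaustive: int, rng):
    n = cov.size
    total = math.factorial(n)
    if total <= max_exhaustive:
        def gen():
            for perm in itertools.permutations(range(n)):
                yield cov[list(perm)]

        return gen(), total, "exhaustive"

    def gen_mc():
        for _ in range(n_perm):
            yield cov[rng.permutation(n)]

    return gen_mc(), n_perm, "monte_carlo"


def permutation_inference(
    images,
    design,
    statistic: str = "group",
    mask: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
    seed: int | None = 0,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    connectivity: int = 6,
    two_sided: bool = False,
    max_exhaustive: int = 20000,
    subject_ids=None,
    r_to_t: bool = False,
) -> PermutationInference:
    """Max-statistic permutation FWE correction of a TFCE-enhanced map.

    For the group design, permutations relabel group membership; for the
    correlation design they shuffle the covariate across subjects.  All
    distinct relabelings are enumerated when their number does not exceed
    ``max_exhaustive`` (the 7-vs-6 design has C(13,6) = 1716); otherwise
    ``n_perm`` Monte-Carlo permutations are drawn and the identity
    permutation is included in the null, so the smallest attainable
    corrected p is 1/(n_perm + 1).

    ``r_to_t`` converts correlation maps to the equivalent t statistic
    before enhancement (a monotone transform; off by default, enhancement
    is on the r scale).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    for a in alpha_levels:
        if not 0 < a < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
    if subject_ids is not None and len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subjects in design")

    data, template = _stack(images)
    if mask is None:
        mask = _full_mask(template.shape)
    mask = np.asarray(mask, dtype=bool)
    X = data[:, mask]
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    deltas = connectivity_structure(connectivity)

    if statistic == "group":
        design = np.asarray(design)
        levels = np.unique(design)
        if levels.size != 2:
            raise ValueError("group design requires exactly two levels")
        is_a_obs = design == levels[0]
        n_a = int(is_a_obs.sum())
        if n_a < 2 or n - n_a < 2:
            raise ValueError("need at least 2 subjects per group")
        df = n - 2

        def stat_of(is_a):
            return _group_t_flat(X, is_a)

        perms, n_eff, scheme = _group_relabelings(n, n_a, n_perm, max_exhaustive, rng)
        obs_flat = stat_of(is_a_obs)
        kind = "t"
        meta = {"df": df}
    elif statistic == "correlation":
        cov = np.asarray(design, dtype=np.float64)
        if cov.size != n:
            raise ValueError("one covariate value per image is required")
        if n < 4:
            raise ValueError("correlation design requires n >= 4")
        if np.isclose(cov.std(), 0.0):
            raise ValueError("covariate is constant")

        if r_to_t:
            dfr = n - 2

            def stat_of(c):
                r = _corr_r_flat(X, c)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = r * np.sqrt(dfr / np.maximum(1.0 - r**2, 1e-300))
                return t

        else:

            def stat_of(c):
                return _corr_r_flat(X, c)

        perms, n_eff, scheme = _covariate_permutations(cov, n_perm, max_exhaustive, rng)
        obs_flat = stat_of(cov)
        kind = "r"
        meta = {"n": n}
    else:
        raise ValueError("statistic must be 'group' or 'correlation'")

    vol = np.zeros(template.shape)
    vol[mask] = obs_flat
    statmap = StatMap(template.with_values(vol), kind=kind, mask=mask, **meta)
    observed = tfce_enhance(statmap, E=E, H=H, n_steps=n_steps, connectivity=connectivity)

    buf = np.zeros(template.shape)
    null_pos = np.empty(n_eff)
    null_neg = np.empty(n_eff)
    for i, perm in enumerate(perms):
        s = stat_of(perm)
        buf[mask] = s
        pos = _tfce_part(np.maximum(buf, 0.0), E, H, n_steps, deltas)
        neg = _tfce_part(np.maximum(-buf, 0.0), E, H, n_steps, deltas)
        null_pos[i] = pos.max()
        null_neg[i] = neg.max()

    def corrected(null_max: np.ndarray, obs_vals: np.ndarray) -> np.ndarray:
        srt = np.sort(null_max)
        ge = srt.size - np.searchsorted(srt, obs_vals.ravel(), side="left")
        if scheme == "exhaustive":
            p = ge / srt.size
        else:
            p = (1.0 + ge) / (srt.size + 1.0)
        return p.reshape(obs_vals.shape)

    if two_sided:
        null_both = np.maximum(null_pos, null_neg)
        p_both = corrected(null_both, observed.combined)
        p_pos = p_neg = p_both
    else:
        p_pos = corrected(null_pos, observed.enhanced_pos.values)
        p_neg = corrected(null_neg, observed.enhanced_neg.values)

    stat_vals = statmap.image.values
    p_map = np.ones(template.shape)
    posv = mask & (stat_vals > 0)
    negv = mask & (stat_vals < 0)
    p_map[posv] = p_pos[posv]
    p_map[negv] = p_neg[negv]

    def as_img(arr):
        out = np.ones(template.shape)
        out[mask] = arr[mask]
        return template.with_values(out)

    return PermutationInference(
        statmap=statmap,
        observed=observed,
        corrected_p=template.with_values(p_map),
        corrected_p_pos=as_img(p_pos),
        corrected_p_neg=as_img(p_neg),
        null_max_pos=null_pos,
        null_max_neg=null_neg,
        n_effective=n_eff,
        scheme=scheme,
        seed=seed,
        two_sided=two_sided,
        alpha_levels=tuple(alpha_levels),
    )


def threshold_map(inference: PermutationInference, alpha: float) -> Image3D:
    """Signed binary map of voxels with corrected p < alpha.

    +1 marks significant voxels with positive statistic (hypermetabolism /
    positive correlation), -1 negative ones.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    stat = inference.statmap.image.values
    mask = inference.statmap.mask
    p = inference.corrected_p.values
    out = np.zeros(stat.shape, dtype=np.int8)
    if alpha == 1.0:
        out[mask & (stat >= 0)] = 1
        out[mask & (stat < 0)] = -1
        return inference.statmap.image.with_values(out)
    out[mask & (p < alpha) & (stat > 0)] = 1
    out[mask & (p < alpha) & (stat < 0)] = -1
    return inference.statmap.image.with_values(out)


def clusters_to_vois(
    thresholded: Image3D,
    statmap: StatMap | None = None,
    connectivity: int = 6,
    atlas=None,
) -> list[ClusterVOI]:
    """Connected components of a signed threshold map, one VOI per cluster.

    Clusters are named by the majority atlas region they overlap (excluding
    parenchyma unless nothing else overlaps); without an atlas they are
    numbered by sign and descending size.
    """
    from scipy import ndimage

    structure = np.zeros((3, 3, 3), dtype=bool)
    for d in connectivity_structure(connectivity):
        structure[tuple(d + 1)] = True
    structure[1, 1, 1] = True

    signed = np.asarray(thresholded.values)
    stat_vals = statmap.image.values if statmap is not None else signed.astype(float)
    vois: list[ClusterVOI] = []
    for sign in (1, -1):
        labels, n_clusters = ndimage.label(signed == sign, structure=structure)
        for lab in range(1, n_clusters + 1):
            idx = np.nonzero(labels == lab)
            stats_here = stat_vals[idx]
            peak = float(stats_here[np.argmax(np.abs(stats_here))])
            name = f"cluster_{'pos' if sign > 0 else 'neg'}_{lab}"
            if atlas is not None:
                region_labels = atlas.labels[idx]
                region_labels = region_labels[region_labels > 0]
                named = region_labels[region_labels != 1]  # prefer non-parenchyma
                pool = named if named.size else region_labels
                if pool.size:
                    majority = int(np.bincount(pool).argmax())
                    name = atlas.names[majority]
            vois.append(
                ClusterVOI(
                    name=name,
                    sign=sign,
                    size=int(idx[0].size),
                    peak_stat=peak,
                    centroid_ijk=tuple(float(i.mean()) for i in idx),
                    indices=idx,
                )
            )
    vois.sort(key=lambda v: -v.size)
    return vois
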