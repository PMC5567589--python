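"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's algorithms and scipy's labelling:
TFCE recomputes connected components from scratch at every threshold with
its own breadth-first search; the smoothing oracle is a direct dense
convolution; the split-plot ANOVA oracle is a cell-means decomposition.
"""

from __future__ import annotations

import numpy as np


def neighbours(connectivity: int):
    out = []
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
                out.append((dx, dy, dz))
    return out


def component_of(above: np.ndarray, start, offsets) -> set:
    """BFS connected component of `start` within the boolean mask `above`."""
    comp = {start}
    frontier = [start]
    shape = above.shape
    while frontier:
        x, y, z = frontier.pop()
        for dx, dy, dz in offsets:
            w = (x + dx, y + dy, z + dz)
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and above[w]
                and w not in comp
            ):
                comp.add(w)
                frontier.append(w)
    return comp


def brute_force_tfce(stat: np.ndarray, E, H, n_steps, connectivity) -> np.ndarray:
    """Threshold-sum TFCE of both signs, components rebuilt per threshold."""
    offsets = neighbours(connectivity)
    out = np.zeros(stat.shape)
    for part in (np.maximum(stat, 0.0), np.maximum(-stat, 0.0)):
        hmax = part.max()
        if hmax <= 0:
            continue
        dh = hmax / n_steps
        for k in range(1, n_steps + 1):
            h = k * dh
            above = part >= h
            seen = set()
            for idx in zip(*np.nonzero(above)):
                if idx in seen:
                    continue
                comp = component_of(above, idx, offsets)
                seen |= comp
                contrib = len(comp) ** E * h**H * dh
                for v in comp:
                    out[v] += contrib
    return out


def brute_force_gaussian(image: np.ndarray, sigmas, truncate=4.0) -> np.ndarray:
    """Direct dense convolution with a sampled, normalised Gaussian kernel."""
    radii = [int(truncate * s + 0.5) for s in sigmas]
    ax = [np.exp(-0.5 * (np.arange(-r, r + 1) / s) ** 2) for r, s in zip(radii, sigmas)]
    ax = [a / a.sum() for a in ax]
    kernel = ax[0][:, None, None] * ax[1][None, :, None] * ax[2][None, None, :]
    rx, ry, rz = radii
    padded = np.pad(image, ((rx, rx), (ry, ry), (rz, rz)))
    out = np.zeros_like(image, dtype=float)
    for i in range(kernel.shape[0]):
        for j in range(kernel.shape[1]):
            for k in range(kernel.shape[2]):
                out += (
                    kernel[i, j, k]
                    * padded[
                        i : i + image.shape[0],
                        j : j + image.shape[1],
                        k : k + image.shape[2],
                    ]
                )
    return out


def brute_force_split_plot(values, subjects, groups, levels):
    """Cell-means sums of squares for the two-way mixed design.

    values: observation per (subject, level); all inputs 1D aligned arrays.
    Returns dict of SS terms computed from explicit cell/marginal means.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    groups = np.asarray(groups)
    levels = np.asarray(levels)
    subj_ids = list(dict.fromkeys(subjects))
    lvl_ids = list(dict.fromkeys(levels))
    grp_of = {s: groups[subjects == s][0] for s in subj_ids}
    grp_ids = list(dict.fromkeys(grp_of[s] for s in subj_ids))
    p = len(lvl_ids)
    grand = values.mean()

    def mean_where(m):
        return values[m].mean()

    ss_total = float(((values - grand) ** 2).sum())
    subj_mean = {s: mean_where(subjects == s) for s in subj_ids}
    grp_mean = {g: mean_where(groups == g) for g in grp_ids}
    lvl_mean = {l: mean_where(levels == l) for l in lvl_ids}
    cell_mean = {
        (g, l): mean_where((groups == g) & (levels == l))
        for g in grp_ids
        for l in lvl_ids
    }
    n_g = {g: sum(grp_of[s] == g for s in subj_ids) for g in grp_ids}

    ss_treat = p * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in grp_ids)
    ss_subj = p * sum((subj_mean[s] - grp_mean[grp_of[s]]) ** 2 for s in subj_ids)
    ss_lvl = len(subj_ids) * sum((lvl_mean[l] - grand) ** 2 for l in lvl_ids)
    ss_int = sum(
        n_g[g] * (cell_mean[g, l] - grp_mean[g] - lvl_mean[l] + grand) ** 2
        for g in grp_ids
        for l in lvl_ids
    )
    ss_err = 0.0
    for i, (v, s, l) in enumerate(zip(values, subjects, levels)):
        g = grp_of[s]
        ss_err += (v - subj_mean[s] - cell_mean[g, l] + grp_mean[g]) ** 2
    return {
        "total": ss_total,
        "treatment": ss_treat,
        "subjects": ss_subj,
        "within_factor": ss_lvl,
        "interaction": ss_int,
        "error_within": ss_err,
    }
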