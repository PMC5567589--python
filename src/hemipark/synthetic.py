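"""Synthetic phantom cohorts: atlas, PET images and gait runs.

The generator plants the statistical structure the downstream analysis
assumes — a two-group cohort (default 7 lesioned vs 6 sham), lateralized
FDOPA signal loss scaled by a per-animal depletion severity, FDG images
with severity-proportional hypo-/hypermetabolic regions, and CatWalk-like
footfall event streams whose summary gait parameters depend linearly on
severity — so every stage of the pipeline is testable without real data.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Image3D, LabelAtlas
from .image_prep import gaussian_smooth

__all__ = [
    "RegionSpec",
    "CohortSpec",
    "SubjectRecord",
    "GaitModel",
    "GaitRun",
    "FootfallEvent",
    "PAWS",
    "DEFAULT_GRID",
    "DEFAULT_VOXEL_SIZE",
    "SEVERITY_VOI",
    "default_region_specs",
    "generate_atlas",
    "generate_cohort",
    "cohort_to_frame",
    "simulate_fdopa",
    "simulate_fdg",
    "simulate_gait_runs",
    "runs_to_frame",
    "frame_to_runs",
    "default_effect_table",
]

#: Reconstruction grid of the scanner protocol the phantom mimics.
DEFAULT_GRID = (40, 48, 24)
DEFAULT_VOXEL_SIZE = (0.38, 0.38, 0.82)

#: Sub-VOIs pooled into the combined striatum + accumbens severity VOI.
SEVERITY_VOI = (
    "striatum_medial",
    "striatum_lateral",
    "accumbens_core",
    "accumbens_shell_medial",
    "accumbens_shell_lateral",
)

PAWS = ("CF", "CH", "IF", "IH")


@dataclass
class RegionSpec:
    """Ellipsoidal region: mirrored pair (``paired=True``) or midline blob.

    ``center`` and ``radii`` are in voxel index units; for paired regions the
    center describes the left-hemisphere member and the right member is its
    exact mirror across the lateral axis.
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    paired: bool = True


def default_region_specs() -> list[RegionSpec]:
    """Region layout loosely following a rat brain in the default grid.

    x (lateral) 0..39, y (rostro-caudal, caudal at low y) 0..47, z 0..23.
    """
    return [
        RegionSpec("striatum_medial", (13.0, 30.0, 13.0), (2.6, 3.5, 2.6)),
        RegionSpec("striatum_lateral", (8.2, 30.0, 13.0), (2.0, 3.5, 2.6)),
        RegionSpec("accumbens_core", (12.0, 37.0, 8.5), (1.8, 1.8, 1.8)),
        RegionSpec("accumbens_shell_medial", (14.8, 37.0, 8.0), (1.4, 1.5, 1.5)),
        RegionSpec("accumbens_shell_lateral", (9.2, 37.0, 8.0), (1.4, 1.5, 1.5)),
        RegionSpec("caudal_striatum", (8.8, 23.5, 13.0), (2.0, 2.4, 2.2)),
        RegionSpec("rfa", (10.0, 40.5, 17.0), (2.0, 2.0, 2.0)),
        RegionSpec("lpth", (13.0, 19.5, 12.0), (2.0, 2.0, 2.0)),
        RegionSpec("mlr", (11.0, 13.5, 11.0), (2.0, 2.0, 2.0)),
        RegionSpec("cerebellum_lobule_v", (8.5, 6.0, 13.0), (2.0, 2.0, 2.2)),
        RegionSpec("cerebellum", (19.5, 5.0, 12.0), (5.5, 4.0, 5.5), paired=False),
    ]


def _hemisphere_suffix(name: str, side: str) -> str:
    return f"{name}_{side}"


def generate_atlas(
    grid_dims: tuple[int, int, int] = DEFAULT_GRID,
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    region_specs: list[RegionSpec] | None = None,
    lateral_axis: int = 0,
    brain_radius_fraction: float = 0.94,
) -> LabelAtlas:
    """Build a procedural label atlas of mirrored ellipsoid pairs.

    Paired regions become ``<name>_L`` / ``<name>_R`` with identical voxel
    counts by construction; the remaining brain ellipsoid is labelled
    ``parenchyma``.  Overlapping region definitions raise, naming both.
    """
    if grid_dims[lateral_axis] % 2 != 0:
        raise ValueError("grid must be even along the lateral axis")
    if region_specs is None:
        region_specs = default_region_specs()

    nx, ny, nz = grid_dims
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )

    def ellipsoid(center, radii):
        return (
            ((ix - center[0]) / radii[0]) ** 2
            + ((iy - center[1]) / radii[1]) ** 2
            + ((iz - center[2]) / radii[2]) ** 2
        ) <= 1.0

    labels = np.zeros(grid_dims, dtype=np.int32)
    names: dict[int, str] = {}
    pairs: dict[str, str] = {}
    next_label = 2  # 1 reserved for parenchyma

    def place(name: str, mask: np.ndarray) -> None:
        nonlocal next_label
        if not mask.any():
            raise ValueError(f"region {name!r} occupies no voxels")
        clash = labels[mask]
        if (clash > 0).any():
            other = names[int(clash[clash > 0][0])]
            raise ValueError(f"region definitions overlap: {name!r} and {other!r}")
        labels[mask] = next_label
        names[next_label] = name
        next_label += 1

    n_lat = grid_dims[lateral_axis]
    for spec in region_specs:
        mask = ellipsoid(spec.center, spec.radii)
        if spec.paired:
            left = _hemisphere_suffix(spec.name, "L")
            right = _hemisphere_suffix(spec.name, "R")
            place(left, mask)
            # exact mirror: index i -> n-1-i along the lateral axis
            place(right, np.flip(mask, axis=lateral_axis))
            pairs[left] = right
            pairs[right] = left
        else:
            place(spec.name, mask)

    center = tuple((d - 1) / 2.0 for d in grid_dims)
    radii = tuple(brain_radius_fraction * d / 2.0 for d in grid_dims)
    brain = ellipsoid(center, radii)
    parenchyma = brain & (labels == 0)
    labels[parenchyma] = 1
    names[1] = "parenchyma"
    # stray region voxels outside the brain ellipsoid stay in the brain mask
    return LabelAtlas(labels, names, voxel_size_mm, lateral_axis, pairs)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "lesion" | "sham"
    injection_side: str  # "left" | "right"
    severity: float  # planted dopamine-depletion severity in [0, 1]


def default_effect_table() -> list[tuple[str, str, float]]:
    """FDG effects: (region, hemisphere relative to lesion, slope per unit severity).

    Negative slopes are ipsilesional hypometabolism, positive slopes
    contralesional hypermetabolism, mirroring the imbalance the analysis is
    designed to detect.
    """
    return [
        ("striatum_medial", "ipsi", -0.15),
        ("rfa", "ipsi", -0.20),
        ("lpth", "ipsi", -0.22),
        ("caudal_striatum", "contra", 0.20),
        ("mlr", "contra", 0.25),
        ("cerebellum_lobule_v", "contra", 0.15),
    ]


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``severity_distribution`` is either ``("uniform", lo, hi)`` or
    ``("point", value)`` over [0, 1] and applies to lesioned animals only;
    sham severities are 0 before noise.
    """

    n_lesion: int = 7
    n_sham: int = 6
    severity_distribution: tuple = ("uniform", 0.3, 0.9)
    injection_side_rule: str = "randomized"  # "all-left" | "randomized"
    noise_sd_fdopa: float = 0.05
    noise_sd_fdg: float = 0.05
    noise_smooth_fwhm_mm: float = 0.0
    effect_table: list[tuple[str, str, float]] = field(
        default_factory=default_effect_table
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesion < 2 or self.n_sham < 2:
            raise ValueError("need at least 2 subjects per group")
        kind = self.severity_distribution[0]
        if kind == "uniform":
            _, lo, hi = self.severity_distribution
            if not (0 <= lo <= hi <= 1):
                raise ValueError("severity support must lie in [0, 1]")
        elif kind == "point":
            if not 0 <= self.severity_distribution[1] <= 1:
                raise ValueError("severity must lie in [0, 1]")
        else:
            raise ValueError(f"unknown severity distribution {kind!r}")
        if self.injection_side_rule not in ("all-left", "randomized"):
            raise ValueError("injection_side_rule must be 'all-left' or 'randomized'")

    def validate_regions(self, atlas: LabelAtlas) -> None:
        for region, _, _ in self.effect_table:
            atlas.label_of(_hemisphere_suffix(region, "L"))


def _draw_severity(spec: CohortSpec, rng: np.random.Generator) -> float:
    kind = spec.severity_distribution[0]
    if kind == "uniform":
        _, lo, hi = spec.severity_distribution
        return float(rng.uniform(lo, hi))
    return float(spec.severity_distribution[1])


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a reproducible cohort of subject records with planted severities."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for i in range(spec.n_lesion):
        side = (
            "left"
            if spec.injection_side_rule == "all-left"
            else ("left", "right")[int(rng.integers(2))]
        )
        records.append(
            SubjectRecord(f"lesion{i + 1:02d}", "lesion", side, _draw_severity(spec, rng))
        )
    for i in range(spec.n_sham):
        side = (
            "left"
            if spec.injection_side_rule == "all-left"
            else ("left", "right")[int(rng.integers(2))]
        )
        records.append(SubjectRecord(f"sham{i + 1:02d}", "sham", side, 0.0))
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "injection_side": [r.injection_side for r in records],
            "severity_planted": [r.severity for r in records],
        }
    )


# ---------------------------------------------------------------------------
# PET images

_FDOPA_STRIATAL_UPTAKE = 2.5
_FDG_TEMPLATE = {"parenchyma": 1.0, "cerebellum": 1.05}


def _lesion_mask(atlas: LabelAtlas, regions, side: str) -> np.ndarray:
    suffix = "L" if side == "left" else "R"
    return atlas.mask([_hemisphere_suffix(r, suffix) for r in regions])


def _subject_rng(spec_seed: int, subject: SubjectRecord, tag: int) -> np.random.Generator:
    # stable per-subject stream independent of cohort iteration order
    ident = abs(hash((subject.subject_id, tag))) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([spec_seed, tag, ident]))


def _apply_noise(
    values: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    smooth_fwhm_mm: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    if sd <= 0:
        return values
    noise = rng.normal(0.0, sd, size=values.shape)
    if smooth_fwhm_mm > 0:
        # spatially correlated noise, rescaled back to the requested sd
        img = gaussian_smooth(Image3D(noise, voxel_size), smooth_fwhm_mm)
        noise = img.values
        s = noise.std()
        if s > 0:
            noise *= sd / s
    return values * (1.0 + noise)


def simulate_fdopa(
    subject: SubjectRecord, atlas: LabelAtlas, spec: CohortSpec
) -> Image3D:
    """FDOPA phantom: striatal+accumbens uptake scaled by (1 - severity) ipsilesionally.

    The whole striatal signal on the lesioned side is multiplied by
    ``1 - severity``, so complete depletion (s = 1) zeroes the ipsilesional
    VOI and the downstream severity statistic returns exactly 1.  Cerebellum
    is unaffected (it is the reference region).
    """
    base = np.ones(atlas.shape, dtype=np.float64)
    base[~atlas.brain_mask()] = 0.0
    striatal = atlas.mask(
        [_hemisphere_suffix(r, s) for r in SEVERITY_VOI for s in ("L", "R")]
    )
    base[striatal] = _FDOPA_STRIATAL_UPTAKE
    ipsi = _lesion_mask(atlas, SEVERITY_VOI, subject.injection_side)
    base[ipsi] *= 1.0 - subject.severity
    rng = _subject_rng(spec.seed, subject, 1)
    vals = _apply_noise(
        base, spec.noise_sd_fdopa, rng, spec.noise_smooth_fwhm_mm, atlas.voxel_size
    )
    return Image3D(vals, atlas.voxel_size, atlas.lateral_axis)


def fdg_template(atlas: LabelAtlas) -> np.ndarray:
    """Baseline FDG intensity pattern shared by all subjects."""
    base = np.zeros(atlas.shape, dtype=np.float64)
    brain = atlas.brain_mask()
    base[brain] = _FDG_TEMPLATE["parenchyma"]
    base[atlas.mask("cerebellum")] = _FDG_TEMPLATE["cerebellum"]
    striatal = atlas.mask(
        [_hemisphere_suffix(r, s) for r in SEVERITY_VOI for s in ("L", "R")]
    )
    base[striatal] = 1.2
    return base


def simulate_fdg(
    subject: SubjectRecord, atlas: LabelAtlas, spec: CohortSpec
) -> Image3D:
    """FDG phantom: per-region mean shifted by slope x severity, plus noise.

    Ipsi/contra in the effect table is resolved from the subject's recorded
    injection side, so images are generated in subject space and flipped
    later by the pipeline exactly as acquired data would be.
    """
    spec.validate_regions(atlas)
    base = fdg_template(atlas)
    s = subject.severity
    ipsi_suffix = "L" if subject.injection_side == "left" else "R"
    contra_suffix = "R" if ipsi_suffix == "L" else "L"
    for region, hemi, slope in spec.effect_table:
        if hemi == "ipsi":
            suffixes = (ipsi_suffix,)
        elif hemi == "contra":
            suffixes = (contra_suffix,)
        else:  # "both"
            suffixes = (ipsi_suffix, contra_suffix)
        for suf in suffixes:
            mask = atlas.mask(_hemisphere_suffix(region, suf))
            base[mask] *= 1.0 + slope * s
    rng = _subject_rng(spec.seed, subject, 2)
    vals = _apply_noise(
        base, spec.noise_sd_fdg, rng, spec.noise_smooth_fwhm_mm, atlas.voxel_size
    )
    return Image3D(vals, atlas.voxel_size, atlas.lateral_axis)


# ---------------------------------------------------------------------------
# gait


@dataclass
class FootfallEvent:
    paw: str
    t_contact: float
    t_lift: float
    x: float
    y: float
    print_area: float


@dataclass
class GaitRun:
    run_id: str
    events: list[FootfallEvent]
    walkway_length_cm: float = 39.0


def _default_slopes() -> dict[str, dict[str, float]]:
    # signs follow the depletion-severity correlation pattern: durations and
    # the ipsilesional-hind print area rise with severity, stride falls
    return {
        "swing_duration": {"CF": 0.080, "CH": 0.040, "IF": 0.025, "IH": 0.020},
        "stance_duration": {"CF": 0.080, "CH": 0.100, "IF": 0.105, "IH": 0.110},
        "stride_length": {"CF": -5.0, "CH": -5.0, "IF": -5.0, "IH": -5.0},
        "print_area": {"CF": 0.00, "CH": 0.05, "IF": 0.10, "IH": 0.55},
    }


@dataclass
class GaitModel:
    """Linear severity -> gait-parameter model used by the run generator.

    ``baselines`` are healthy-animal per-step targets (s, s, cm, cm^2);
    ``slopes`` the signed change per unit depletion severity per paw;
    ``animal_sd`` between-animal residual noise and ``run_sd`` run-to-run
    noise on the realised per-run parameter.  Steps per paw are derived
    from the walkway length and realised stride unless fixed.
    """

    baselines: dict[str, float] = field(
        default_factory=lambda: {
            "swing_duration": 0.10,
            "stance_duration": 0.25,
            "stride_length": 16.0,
            "print_area": 1.8,
        }
    )
    slopes: dict[str, dict[str, float]] = field(default_factory=_default_slopes)
    animal_sd: dict[str, float] = field(
        default_factory=lambda: {
            "swing_duration": 0.015,
            "stance_duration": 0.020,
            "stride_length": 1.0,
            "print_area": 0.15,
        }
    )
    run_sd_fraction: float = 0.5  # run-level sd as a fraction of animal_sd
    steps_per_run: int | None = None  # per paw; None -> derived from walkway
    walkway_length_cm: float = 39.0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.baselines.values()):
            raise ValueError("baselines must be positive")
        if self.walkway_length_cm <= 0:
            raise ValueError("walkway length must be positive")

    def targets(self, paw: str, severity: float) -> dict[str, float]:
        out = {
            p: self.baselines[p] + self.slopes[p][paw] * severity
            for p in self.baselines
        }
        bad = [p for p in out if out[p] <= 0]
        if bad:
            raise ValueError(
                f"infeasible gait model: non-positive target {bad[0]} for paw {paw}"
            )
        return out


# diagonal gait: CF+IH strike together, alternating with CH+IF
_PHASE = {"CF": 0.0, "IH": 0.0, "CH": 0.5, "IF": 0.5}
_Y_OFFSET = {"CF": 1.5, "CH": -1.5, "IF": 1.5, "IH": -1.5}
_X_START = {"CF": 6.0, "IF": 6.0, "CH": 0.0, "IH": 0.0}


def simulate_gait_runs(
    subject: SubjectRecord,
    model: GaitModel,
    n_runs: int = 9,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[GaitRun]:
    """Emit compliant footfall event streams for one animal.

    Within a run each paw keeps constant realised swing/stance/stride, so
    the parameters recomputed by the gait module equal the severity-
    dependent targets (plus the per-animal and per-run noise) exactly and
    the runs trivially satisfy the speed-variation compliance rule.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    animal_eff = {
        p: {paw: rng.normal(0.0, model.animal_sd[p]) for paw in PAWS}
        for p in model.baselines
    }
    runs: list[GaitRun] = []
    for r in range(n_runs):
        events: list[FootfallEvent] = []
        for paw in PAWS:
            tgt = model.targets(paw, subject.severity)
            real = {}
            for p, v in tgt.items():
                v = v + animal_eff[p][paw] + rng.normal(
                    0.0, model.run_sd_fraction * model.animal_sd[p]
                )
                real[p] = max(v, 0.2 * model.baselines[p])  # keep physical
            cycle = real["stance_duration"] + real["swing_duration"]
            if model.steps_per_run is not None:
                n_steps = model.steps_per_run
            else:
                n_steps = int(np.ceil(model.walkway_length_cm / real["stride_length"])) + 1
            n_steps = max(n_steps, 3)
            t0 = _PHASE[paw] * cycle
            for k in range(n_steps):
                tc = t0 + k * cycle
                events.append(
                    FootfallEvent(
                        paw=paw,
                        t_contact=tc,
                        t_lift=tc + real["stance_duration"],
                        x=_X_START[paw] + k * real["stride_length"],
                        y=_Y_OFFSET[paw],
                        print_area=real["print_area"],
                    )
                )
        events.sort(key=lambda e: (e.t_contact, e.paw))
        runs.append(
            GaitRun(
                run_id=f"{subject.subject_id}_run{r + 1}",
                events=events,
                walkway_length_cm=model.walkway_length_cm,
            )
        )
    return runs


def runs_to_frame(runs: list[GaitRun]) -> pd.DataFrame:
    """Footfall CSV layout: run_id, paw, t_contact_s, t_lift_s, x_cm, y_cm, print_area_cm2."""
    rows = []
    for run in runs:
        for e in run.events:
            rows.append(
                (run.run_id, e.paw, e.t_contact, e.t_lift, e.x, e.y, e.print_area)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "paw",
            "t_contact_s",
            "t_lift_s",
            "x_cm",
            "y_cm",
            "print_area_cm2",
        ],
    )


def frame_to_runs(frame: pd.DataFrame, walkway_length_cm: float = 39.0) -> list[GaitRun]:
    runs = []
    for run_id, grp in frame.groupby("run_id", sort=True):
        events = [
            FootfallEvent(
                paw=row.paw,
                t_contact=float(row.t_contact_s),
                t_lift=float(row.t_lift_s),
                x=float(row.x_cm),
                y=float(row.y_cm),
                print_area=float(row.print_area_cm2),
            )
            for row in grp.itertuples()
        ]
        events.sort(key=lambda e: (e.t_contact, e.paw))
        runs.append(GaitRun(str(run_id), events, walkway_length_cm))
    return runs
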