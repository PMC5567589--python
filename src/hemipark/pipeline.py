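"""End-to-end pipeline: severity, SPM maps, gait statistics, correlations.

One :class:`PipelineConfig` drives the full analysis on a synthetic cohort
or on files on disk; given the same config and seed the results JSON is
byte-identical.  Every output embeds the seed and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gait as gaitmod
from . import image_prep, spm, synthetic, voi
from .core import Image3D, LabelAtlas

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("hemipark")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str, subject: str | None = None):
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"{where}: {detail}")
        self.stage = stage
        self.subject = subject


@dataclass
class PipelineConfig:
    output_dir: str = "hemipark_out"
    seed: int = 0
    simulate: bool = True  # generate the cohort instead of reading paths
    # input paths (used when simulate=False)
    atlas_path: str | None = None
    metadata_path: str | None = None
    fdopa_dir: str | None = None
    fdg_dir: str | None = None
    gait_path: str | None = None
    # preprocessing
    smoothing_fwhm_mm: float = 1.5
    severity_on_smoothed: bool = False
    # TFCE / permutation
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_n_steps: int = 100
    connectivity: int = 6
    n_perm: int = 1000
    max_exhaustive: int = 20000
    two_sided: bool = False
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    cluster_alpha: float = 0.01  # clusters at the stricter level become VOIs
    # gait
    compliance_max_duration_s: float = 5.0
    compliance_max_speed_variation_pct: float = 60.0
    posthoc_scheme: str = "holm"
    gait_n_runs: int = 9
    # synthetic cohort
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in (*self.alpha_levels, self.cluster_alpha):
            if not 0 < a < 1:
                raise ValueError(f"alpha must lie in (0,1), got {a}")
        if not self.simulate:
            missing = [
                name
                for name in ("atlas_path", "metadata_path", "fdopa_dir", "fdg_dir")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"simulate=False requires paths: {', '.join(missing)}")
            for name in ("atlas_path", "metadata_path"):
                if not Path(getattr(self, name)).exists():
                    raise ValueError(f"{name} does not exist: {getattr(self, name)}")

    def config_hash(self) -> str:
        # output_dir is excluded: the same analysis in two directories is the
        # same analysis
        payload = asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "alpha_levels" in data:
        data["alpha_levels"] = tuple(data["alpha_levels"])
    return PipelineConfig(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out

        return wrapped

    return deco


def _prep_subject_images(
    raw: dict[str, Image3D],
    records,
    atlas: LabelAtlas,
    fwhm: float,
    reference_mask,
    reference_name: str,
    smooth: bool,
):
    """Flip right-injected subjects, optionally smooth, then SUVR-normalise."""
    out = {}
    brain = atlas.brain_mask()
    for rec in records:
        img = raw[rec.subject_id]
        if rec.injection_side == "right":
            img = image_prep.flip_lateral(img)
        if smooth and fwhm > 0:
            img = image_prep.gaussian_smooth(img, fwhm, mask=brain)
        out[rec.subject_id] = image_prep.normalize_suvr(
            img, reference_mask, reference_name
        )
    return out


@_stage("simulate")
def _simulate(config: PipelineConfig):
    spec = synthetic.CohortSpec(seed=config.seed, **config.cohort)
    atlas = synthetic.generate_atlas()
    spec.validate_regions(atlas)
    records = synthetic.generate_cohort(spec)
    fdopa = {r.subject_id: synthetic.simulate_fdopa(r, atlas, spec) for r in records}
    fdg = {r.subject_id: synthetic.simulate_fdg(r, atlas, spec) for r in records}
    model = synthetic.GaitModel()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 977]))
    runs = {
        r.subject_id: synthetic.simulate_gait_runs(
            r, model, n_runs=config.gait_n_runs, rng=rng
        )
        for r in records
    }
    return atlas, records, fdopa, fdg, runs


@_stage("load")
def _load(config: PipelineConfig):
    atlas = image_prep.read_atlas(config.atlas_path)
    meta = pd.read_csv(config.metadata_path)
    records = [
        synthetic.SubjectRecord(
            row.subject_id,
            row.group,
            row.injection_side,
            float(getattr(row, "severity_planted", np.nan)),
        )
        for row in meta.itertuples()
    ]
    fdopa = {
        r.subject_id: image_prep.read_volume(Path(config.fdopa_dir) / f"{r.subject_id}.nii")
        for r in records
    }
    fdg = {
        r.subject_id: image_prep.read_volume(Path(config.fdg_dir) / f"{r.subject_id}.nii")
        for r in records
    }
    runs = None
    if config.gait_path:
        frame = pd.read_csv(config.gait_path)
        runs = {}
        for r in records:
            sel = frame[frame.run_id.str.startswith(r.subject_id)]
            runs[r.subject_id] = synthetic.frame_to_runs(sel)
    return atlas, records, fdopa, fdg, runs


@_stage("severity")
def _severity(config, atlas, records, fdopa):
    cereb = atlas.mask("cerebellum")
    suvr = _prep_subject_images(
        fdopa,
        records,
        atlas,
        config.smoothing_fwhm_mm,
        cereb,
        "cerebellum",
        smooth=config.severity_on_smoothed,
    )
    rows = []
    scores = {}
    for rec in records:
        score = voi.depletion_severity(
            suvr[rec.subject_id], atlas, ipsi_side="left", subject_id=rec.subject_id
        )
        scores[rec.subject_id] = score.severity
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "severity": score.severity,
            "mean_ipsi": score.mean_ipsi,
            "mean_contra": score.mean_contra,
        }
        for region in synthetic.SEVERITY_VOI:
            for side, sfx in (("ipsi", "L"), ("contra", "R")):
                row[f"{region}_{side}"] = voi.voi_mean(
                    suvr[rec.subject_id], atlas, f"{region}_{sfx}"
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    # paired ipsi vs contra test per sub-VOI within the lesion group
    paired = []
    lesion = table[table.group == "lesion"]
    for region in synthetic.SEVERITY_VOI:
        res = voi.paired_ttest(lesion[f"{region}_ipsi"], lesion[f"{region}_contra"])
        paired.append(
            {"region": region, "t": res.t, "df": res.df, "p": res.p, "n": res.n}
        )
    return table, pd.DataFrame(paired), scores


@_stage("spm")
def _spm(config, atlas, records, fdg, severities):
    brain = atlas.brain_mask()
    suvr = _prep_subject_images(
        fdg, records, atlas, config.smoothing_fwhm_mm, brain, "whole_brain", smooth=True
    )
    order = [r.subject_id for r in records]
    images = [suvr[s] for s in order]
    groups = np.array([r.group for r in records])
    common = dict(
        mask=brain,
        n_perm=config.n_perm,
        alpha_levels=config.alpha_levels,
        seed=config.seed,
        E=config.tfce_e,
        H=config.tfce_h,
        n_steps=config.tfce_n_steps,
        connectivity=config.connectivity,
        two_sided=config.two_sided,
        max_exhaustive=config.max_exhaustive,
        subject_ids=order,
    )
    group_inf = spm.permutation_inference(images, groups, statistic="group", **common)
    sev = np.array([severities[s] for s in order])
    corr_inf = spm.permutation_inference(images, sev, statistic="correlation", **common)
    thr = {
        f"group_{a}": spm.threshold_map(group_inf, a) for a in config.alpha_levels
    } | {f"corr_{a}": spm.threshold_map(corr_inf, a) for a in config.alpha_levels}
    cluster_src = spm.threshold_map(corr_inf, config.cluster_alpha)
    vois = spm.clusters_to_vois(
        cluster_src, corr_inf.statmap, config.connectivity, atlas
    )
    return group_inf, corr_inf, thr, vois, suvr, order


@_stage("gait")
def _gait(config, records, runs):
    groups = {r.subject_id: r.group for r in records}
    kw = dict(
        max_duration_s=config.compliance_max_duration_s,
        max_speed_variation_pct=config.compliance_max_speed_variation_pct,
    )
    paw_table, glob_table = gaitmod.build_param_table(runs, groups, kw)
    anova = {}
    posthoc = {}
    for param in gaitmod.STEP_PARAMS:
        res = gaitmod.mixed_anova(paw_table, param)
        anova[param] = res.table
        posthoc[param] = gaitmod.posthoc_pairwise(
            paw_table, param, scheme=config.posthoc_scheme
        )
    return paw_table, glob_table, anova, posthoc


@_stage("correlate")
def _correlate(config, records, severities, paw_table, glob_table, vois, suvr, atlas, order):
    sev = {r.subject_id: severities[r.subject_id] for r in records}
    rows = []
    for param in gaitmod.STEP_PARAMS:
        for paw in synthetic.PAWS:
            sub = paw_table[paw_table.paw == paw].set_index("animal_id")
            x = [sev[a] for a in sub.index]
            res = gaitmod.correlate(x, sub[param], "severity", f"{param}_{paw}")
            rows.append(
                {
                    "x": "severity",
                    "y": param,
                    "paw": paw,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    gl = glob_table.set_index("animal_id")
    for param in gaitmod.GLOBAL_PARAMS:
        x = [sev[a] for a in gl.index]
        res = gaitmod.correlate(x, gl[param], "severity", param)
        rows.append(
            {"x": "severity", "y": param, "paw": "global", "r": res.r, "p": res.p, "n": res.n}
        )
    sev_gait = pd.DataFrame(rows)

    # cluster-VOI metabolism vs gait parameters
    voi_rows = []
    for cluster in vois:
        means = {
            s: float(np.asarray(suvr[s].values)[cluster.indices].mean()) for s in order
        }
        for param in gaitmod.STEP_PARAMS:
            for paw in synthetic.PAWS:
                sub = paw_table[paw_table.paw == paw].set_index("animal_id")
                res = gaitmod.correlate(
                    [means[a] for a in sub.index], sub[param], cluster.name, param
                )
                voi_rows.append(
                    {
                        "voi": cluster.name,
                        "sign": cluster.sign,
                        "y": param,
                        "paw": paw,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    voi_gait = pd.DataFrame(voi_rows)
    return sev_gait, voi_gait


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle; returns the results dict."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}

    if config.simulate:
        atlas, records, fdopa, fdg, runs = _simulate(config)
    else:
        atlas, records, fdopa, fdg, runs = _load(config)

    severity_table, paired_table, severities = _severity(config, atlas, records, fdopa)
    group_inf, corr_inf, thr_maps, vois, suvr, order = _spm(
        config, atlas, records, fdg, severities
    )
    results: dict = {
        **meta,
        "n_lesion": sum(r.group == "lesion" for r in records),
        "n_sham": sum(r.group == "sham" for r in records),
        "severity": {
            r.subject_id: round(severities[r.subject_id], 6) for r in records
        },
        "spm": {
            "scheme": group_inf.scheme,
            "n_effective": group_inf.n_effective,
            "group_min_p": float(
                group_inf.corrected_p.values[group_inf.statmap.mask].min()
            ),
            "corr_min_p": float(
                corr_inf.corrected_p.values[corr_inf.statmap.mask].min()
            ),
            "n_significant": {
                name: int(np.count_nonzero(m.values)) for name, m in thr_maps.items()
            },
            "cluster_vois": [
                {
                    "name": v.name,
                    "sign": v.sign,
                    "size": v.size,
                    "peak": round(v.peak_stat, 6),
                }
                for v in vois
            ],
        },
    }

    if runs is not None:
        paw_table, glob_table, anova, posthoc = _gait(config, records, runs)
        sev_gait, voi_gait = _correlate(
            config, records, severities, paw_table, glob_table, vois, suvr, atlas, order
        )
        results["gait"] = {
            "anova": {
                param: {
                    eff: {
                        "F": round(float(tab.loc[eff, "F"]), 6),
                        "df1": int(tab.loc[eff, "df1"]),
                        "df2": int(tab.loc[eff, "df2"]),
                        "p": round(float(tab.loc[eff, "p"]), 6),
                    }
                    for eff in ("treatment", "paw", "interaction")
                }
                for param, tab in anova.items()
            },
            "mean_average_speed": {
                g: round(
                    float(glob_table[glob_table.group == g]["average_speed"].mean()), 4
                )
                for g in ("lesion", "sham")
            },
        }
        paw_table.to_csv(out_dir / "gait_params_per_paw.csv", index=False)
        glob_table.to_csv(out_dir / "gait_params_global.csv", index=False)
        sev_gait.to_csv(out_dir / "correlations_severity_gait.csv", index=False)
        if not voi_gait.empty:
            voi_gait.to_csv(out_dir / "correlations_voi_gait.csv", index=False)
        for param, tab in posthoc.items():
            tab.to_csv(out_dir / f"posthoc_{param}.csv", index=False)
        results["gait"]["severity_gait_correlations"] = {
            f"{row.y}_{row.paw}": round(float(row.r), 4)
            for row in sev_gait.itertuples()
        }

    severity_table.to_csv(out_dir / "severity.csv", index=False)
    paired_table.to_csv(out_dir / "paired_ttests.csv", index=False)
    image_prep.write_volume(group_inf.statmap.image, out_dir / "group_tmap.nii")
    image_prep.write_volume(corr_inf.statmap.image, out_dir / "corr_rmap.nii")
    image_prep.write_volume(group_inf.corrected_p, out_dir / "group_corrected_p.nii")
    image_prep.write_volume(corr_inf.corrected_p, out_dir / "corr_corrected_p.nii")
    for name, m in thr_maps.items():
        image_prep.write_volume(
            m.with_values(m.values.astype(np.float32)),
            out_dir / f"threshold_{name}.nii",
        )

    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results
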