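"""End-to-end longitudinal experiment: simulate -> preprocess -> connectivity
-> tables/maps/spectra, plus the Y-maze behavioral ANOVA.

The orchestration mirrors the study design: a cohort of rats is scanned
preoperatively and on postoperative days 1, 3 and 9; runs with large
nonlinear baseline drift are excluded (whole rat); seed-based correlation
maps are thresholded at P < 2.5e-5 (one-sided, effective-df-corrected);
supra-threshold voxel counts per region are normalized by each rat's
preoperative count; group maps are Fisher-z one-sample t maps at
P < 0.001 uncorrected; and one designated rat's homotopic timecourses and
spectra are extracted for the preoperative and day-9 sessions.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _version
from .connectivity import (
    CorrelationMap,
    SessionResult,
    correlation_map,
    count_significant,
    effective_df,
    group_tmap,
    normalize_counts,
    r_critical,
    seed_reference,
)
from .errors import ParameterError, PipelineError, SampleSizeError
from .io import (
    RoiSpec,
    default_seeds,
    read_labels,
    read_manifest,
    read_run,
    roi_to_voxels,
    write_labels,
)
from .preprocess import (
    PreprocessSpec,
    detrend_linear,
    drift_statistic,
    drop_dummies,
    lowpass,
    smooth,
)
from .spectra import amplitude_spectrum, homotopic_correlation, percent_signal_change
from .synthetic import (
    CONDITIONS,
    DEFAULT_YMAZE_MEANS,
    DEFAULT_YMAZE_SDS,
    Atlas,
    SyntheticConfig,
    pocd_coupling,
    simulate_cohort,
    simulate_ymaze,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "YMazeAnova",
    "run_experiment",
    "analyze_cohort",
    "ymaze_anova",
    "write_report",
]


@dataclass
class ExperimentConfig:
    """Composition of generator, preprocessing and inference settings."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    n_rats: int = 18
    include_drift_outlier: bool = True
    conditions: tuple[str, ...] = CONDITIONS
    p_threshold: float = 2.5e-5
    group_p: float = 0.001
    sidedness: str = "one"
    ymaze_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YMAZE_MEANS))
    ymaze_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YMAZE_SDS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1 or not 0 < self.group_p < 1:
            raise ParameterError("p thresholds must be in (0, 1)")
        unknown = [c for c in self.conditions if c not in CONDITIONS]
        if unknown:
            raise ParameterError(f"unknown conditions {unknown}; know {CONDITIONS}")
        # one seed stream drives generator and behavioral arm alike
        self.synthetic = dataclasses.replace(self.synthetic, rng_seed=self.rng_seed)

    def seeds(self) -> dict[str, RoiSpec]:
        return default_seeds()

    # -- YAML round trip ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_raw = dict(raw.pop("synthetic", {}))
        coupling_raw = syn_raw.pop("coupling", None)
        if coupling_raw is not None:
            syn_raw["coupling"] = pocd_coupling(
                float(coupling_raw.get("amplitude", 1.2)),
                coupling_raw.get("day9_amplitude"),
            )
        for key in ("grid_shape", "voxel_size_mm", "lff_band_hz", "drift_slope_range",
                    "grid_center_mm", "region_extent_mm"):
            if key in syn_raw and syn_raw[key] is not None:
                syn_raw[key] = tuple(syn_raw[key])
        if "physio" in syn_raw:
            syn_raw["physio"] = tuple(tuple(p) for p in syn_raw["physio"])
        pre_raw = dict(raw.pop("preprocess", {}))
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(
            synthetic=SyntheticConfig(**syn_raw),
            preprocess=PreprocessSpec(**pre_raw),
            **raw,
        )

    def to_dict(self) -> dict:
        syn = dataclasses.asdict(self.synthetic)
        syn["coupling"] = {
            "|".join(key): value for key, value in self.synthetic.coupling.items()
        }
        return {
            "synthetic": syn,
            "preprocess": dataclasses.asdict(self.preprocess),
            "n_rats": self.n_rats,
            "include_drift_outlier": self.include_drift_outlier,
            "conditions": list(self.conditions),
            "p_threshold": self.p_threshold,
            "group_p": self.group_p,
            "sidedness": self.sidedness,
            "ymaze_means": self.ymaze_means,
            "ymaze_sds": self.ymaze_sds,
            "rng_seed": self.rng_seed,
        }


@dataclass
class YMazeAnova:
    """One-way ANOVA across sessions plus preop-vs-day pairwise contrasts."""

    f_statistic: float
    p_value: float
    pairwise: dict[str, tuple[float, float]]  # condition -> (t, unadjusted p)


@dataclass
class ExperimentResult:
    """Everything one experiment run produces."""

    results: pd.DataFrame  # rat_id, condition, seed, region, count, normalized
    summary: pd.DataFrame  # condition, seed, region, mean, sd, n
    excluded: list[tuple[str, str]]  # (rat_id, reason)
    analyzed_rats: list[str]
    group_maps: dict[tuple[str, str], dict[str, np.ndarray]]  # (seed, cond) -> t/p/sig
    spectra: dict[tuple[str, str], dict]  # (region, cond) -> traces and spectra
    ymaze: pd.DataFrame
    ymaze_anova: YMazeAnova
    atlas: Atlas
    metadata: dict
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def ymaze_anova(table: pd.DataFrame, baseline: str = "preop") -> YMazeAnova:
    """One-way ANOVA of trials-to-criterion across conditions.

    Pairwise contrasts are unadjusted two-sample t tests of each
    non-baseline condition against the baseline.  Degenerate all-identical
    data yields F = 0, p = 1.
    """
    conditions = list(dict.fromkeys(table["condition"]))
    if len(conditions) < 2:
        raise SampleSizeError("need >= 2 conditions for an ANOVA")
    groups = []
    for cond in conditions:
        vals = table.loc[table["condition"] == cond, "trials_to_criterion"].to_numpy(float)
        if vals.size < 2:
            raise SampleSizeError(f"condition {cond!r} has < 2 rats")
        groups.append(vals)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        res = stats.f_oneway(*groups)
        f_stat, p_val = float(res.statistic), float(res.pvalue)
    pairwise: dict[str, tuple[float, float]] = {}
    base = table.loc[table["condition"] == baseline, "trials_to_criterion"].to_numpy(float)
    for cond in conditions:
        if cond == baseline:
            continue
        other = table.loc[table["condition"] == cond, "trials_to_criterion"].to_numpy(float)
        if np.ptp(np.concatenate([base, other])) == 0:
            pairwise[cond] = (0.0, 1.0)
        else:
            t_res = stats.ttest_ind(other, base)
            pairwise[cond] = (float(t_res.statistic), float(t_res.pvalue))
    return YMazeAnova(f_statistic=f_stat, p_value=p_val, pairwise=pairwise)


def _count_masks(atlas: Atlas) -> dict[str, np.ndarray]:
    return {name: atlas.mask(name) for name in atlas.region_names}


def _analyze_run(run_pre, seeds, atlas, p_threshold, cutoff_hz, sidedness):
    """All-seed analysis of one preprocessed run -> {seed: (SessionResult, map)}."""
    masks = _count_masks(atlas)
    out = {}
    for seed_name, roi in seeds.items():
        ref = seed_reference(run_pre, roi)
        cmap = correlation_map(run_pre, ref, p_threshold, cutoff_hz, sidedness)
        cmap.seed = roi
        counts = {name: count_significant(cmap, mask) for name, mask in masks.items()}
        counts[f"{roi.region}_both"] = (
            counts[f"{roi.region}_L"] + counts[f"{roi.region}_R"]
        )
        out[seed_name] = (
            SessionResult(run_pre.rat_id, run_pre.condition, seed_name, counts),
            cmap,
        )
    return out


def analyze_cohort(
    manifest: pd.DataFrame,
    atlas: Atlas,
    seeds: dict[str, RoiSpec] | None = None,
    pre_spec: PreprocessSpec | None = None,
    p_threshold: float = 2.5e-5,
    sidedness: str = "one",
    conditions: tuple[str, ...] = CONDITIONS,
    baseline: str = "preop",
    spectra_conditions: tuple[str, ...] = ("preop", "d9"),
    log: list[str] | None = None,
):
    """Preprocess and analyze every rat in a manifest.

    Returns ``(results_df, excluded, analyzed_rats, rat_maps, spectra)``
    where ``rat_maps[(seed, condition)]`` is the list of per-rat correlation
    maps of the analyzed rats and ``spectra`` holds the designated (first
    analyzed) rat's homotopic traces.
    """
    seeds = default_seeds() if seeds is None else seeds
    pre_spec = PreprocessSpec() if pre_spec is None else pre_spec
    log = [] if log is None else log

    rows = []
    excluded: list[tuple[str, str]] = []
    analyzed: list[str] = []
    rat_maps: dict[tuple[str, str], list[CorrelationMap]] = {}
    spectra_bundle: dict[tuple[str, str], dict] = {}
    spectra_done = False

    for rat_id, sub in manifest.groupby("rat_id", sort=True):
        t0 = time.perf_counter()
        try:
            runs = {
                row.condition: read_run(
                    row.path, rat_id=rat_id, condition=row.condition, n_dummy=row.n_dummy
                )
                for row in sub.itertuples()
            }
        except Exception as exc:  # pragma: no cover - I/O context
            raise PipelineError(f"stage=load rat={rat_id}: {exc}") from exc
        missing = [c for c in conditions if c not in runs]
        if missing:
            raise PipelineError(f"stage=load rat={rat_id}: missing sessions {missing}")

        reasons = []
        for cond in conditions:
            score = drift_statistic(runs[cond])
            if score > pre_spec.quad_threshold:
                reasons.append(f"{cond}: nonlinear baseline drift score {score:.2f}")
        if reasons:
            excluded.append((rat_id, "; ".join(reasons)))
            log.append(f"exclude rat={rat_id}: {'; '.join(reasons)}")
            continue

        per_cond: dict[str, dict] = {}
        for cond in conditions:
            try:
                run_pre = _preprocess(runs[cond], pre_spec)
                per_cond[cond] = _analyze_run(
                    run_pre, seeds, atlas, p_threshold, pre_spec.cutoff_hz, sidedness
                )
            except Exception as exc:
                raise PipelineError(f"stage=connectivity rat={rat_id} session={cond}: {exc}") from exc

        for seed_name in seeds:
            preop_counts = per_cond[baseline][seed_name][0].counts
            for cond in conditions:
                result, cmap = per_cond[cond][seed_name]
                result.normalized = normalize_counts(result.counts, preop_counts)
                rat_maps.setdefault((seed_name, cond), []).append(cmap)
                for region, count in result.counts.items():
                    rows.append(
                        {
                            "rat_id": rat_id,
                            "condition": cond,
                            "seed": seed_name,
                            "region": region,
                            "count": count,
                            "normalized": result.normalized[region],
                        }
                    )
        analyzed.append(rat_id)
        if not spectra_done:
            for seed_name, roi in seeds.items():
                for cond in spectra_conditions:
                    if cond not in conditions:
                        continue
                    spectra_bundle[(roi.region, cond)] = _homotopic_traces(
                        runs[cond], roi, pre_spec, rat_id
                    )
            spectra_done = True
        log.append(f"analyzed rat={rat_id} in {time.perf_counter() - t0:.1f}s")

    results = pd.DataFrame(
        rows, columns=["rat_id", "condition", "seed", "region", "count", "normalized"]
    )
    return results, excluded, analyzed, rat_maps, spectra_bundle


def _preprocess(run, spec: PreprocessSpec):
    out = drop_dummies(run)
    out = smooth(out, spec.fwhm_mm, voxel_scale=spec.voxel_scale)
    out = detrend_linear(out)
    out = lowpass(out, spec=spec.filter_spec())
    return out


def _homotopic_traces(run_raw, roi: RoiSpec, pre_spec: PreprocessSpec, rat_id: str) -> dict:
    """Percent-signal-change homotopic traces + spectra for one raw run.

    Percent change is taken against the raw temporal mean (before detrending
    removes it); detrend and low-pass are then applied.  Because percent
    change is an affine map, correlations match the standard chain.
    """
    run = drop_dummies(run_raw)
    run = smooth(run, pre_spec.fwhm_mm, voxel_scale=pre_spec.voxel_scale)
    out: dict = {"rat_id": rat_id, "region": roi.region, "condition": run_raw.condition}
    for side, spec_roi in (("left", roi), ("right", roi.mirrored())):
        idx = roi_to_voxels(spec_roi, run.geometry)
        tc = run.data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)
        tc = percent_signal_change(tc)
        tc = detrend_linear(tc)
        tc = lowpass(tc, run.tr_s, pre_spec.filter_spec())
        out[side] = tc
        out[f"spectrum_{side}"] = amplitude_spectrum(tc, run.tr_s, source=spec_roi.name)
    out["r"] = homotopic_correlation(out["left"], out["right"])
    return out


def run_experiment(config: ExperimentConfig, data_dir=None) -> ExperimentResult:
    """Simulate the cohort, analyze it, and assemble the result bundle.

    ``data_dir`` receives the simulated NIfTI volumes and manifest; when
    omitted a temporary directory is used and cleaned up afterwards.
    Deterministic given ``config.rng_seed``.
    """
    log: list[str] = []
    tmp: TemporaryDirectory | None = None
    if data_dir is None:
        tmp = TemporaryDirectory(prefix="lffconn_")
        data_dir = tmp.name
    try:
        t0 = time.perf_counter()
        manifest = simulate_cohort(
            config.synthetic,
            config.n_rats,
            data_dir,
            include_drift_outlier=config.include_drift_outlier,
        )
        log.append(
            f"simulated {len(manifest)} runs ({config.n_rats} rats x "
            f"{len(CONDITIONS)} sessions) in {time.perf_counter() - t0:.1f}s"
        )
        atlas_labels, atlas_geom = read_labels(Path(data_dir) / "atlas.nii")
        atlas = Atlas(atlas_labels, atlas_geom)

        results, excluded, analyzed, rat_maps, spectra_bundle = analyze_cohort(
            manifest,
            atlas,
            seeds=config.seeds(),
            pre_spec=config.preprocess,
            p_threshold=config.p_threshold,
            sidedness=config.sidedness,
            conditions=config.conditions,
            log=log,
        )
    finally:
        if tmp is not None:
            tmp.cleanup()

    if not analyzed:
        raise PipelineError("stage=analysis: every rat was excluded")

    summary = (
        results.groupby(["condition", "seed", "region"], sort=True)["normalized"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )

    group_maps: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    if len(analyzed) >= 3:
        for (seed_name, cond), maps in rat_maps.items():
            t_map, p_map, sig = group_tmap(maps, p_threshold=config.group_p)
            group_maps[(seed_name, cond)] = {"t": t_map, "p": p_map, "significant": sig}
        log.append(f"group maps for {len(group_maps)} seed x session cells")

    ss = np.random.SeedSequence(config.rng_seed).spawn(2)
    ymaze = simulate_ymaze(
        config.n_rats, config.ymaze_means, config.ymaze_sds, np.random.default_rng(ss[1])
    )
    anova = ymaze_anova(ymaze)
    log.append(
        f"ymaze ANOVA F={anova.f_statistic:.2f} p={anova.p_value:.3g} "
        f"(n={config.n_rats}/condition)"
    )

    df = effective_df(config.synthetic.n_volumes, config.synthetic.tr_s,
                      config.preprocess.cutoff_hz)
    metadata = {
        "software": "lffconn",
        "version": _version,
        "seed": config.rng_seed,
        "p_threshold": config.p_threshold,
        "group_p": config.group_p,
        "sidedness": config.sidedness,
        "effective_df": df,
        "r_critical": r_critical(config.p_threshold, df, config.sidedness),
        "group_test": (
            "one-sample t of Fisher-z(r) against 0, one-sided "
            "(an r-map test 'against 1' is not well defined: r = 1 is the boundary)"
        ),
        "n_rats_simulated": config.n_rats,
        "n_rats_analyzed": len(analyzed),
        "excluded": [{"rat_id": r, "reason": why} for r, why in excluded],
        "config": config.to_dict(),
    }
    return ExperimentResult(
        results=results,
        summary=summary,
        excluded=excluded,
        analyzed_rats=analyzed,
        group_maps=group_maps,
        spectra=spectra_bundle,
        ymaze=ymaze,
        ymaze_anova=anova,
        atlas=atlas,
        metadata=metadata,
        log=log,
    )


def write_report(result: ExperimentResult, out_dir, force: bool = False) -> Path:
    """Write tables, maps, spectra, metadata and log under ``out_dir``.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    if result.results.empty:
        raise ParameterError("result bundle is empty; nothing to write")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    result.results.to_csv(out_dir / "results.csv", index=False, float_format="%.6g")
    result.summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6g")
    pd.DataFrame(result.excluded, columns=["rat_id", "reason"]).to_csv(
        out_dir / "excluded.csv", index=False
    )
    result.ymaze.to_csv(out_dir / "ymaze.csv", index=False)
    anova_payload = {
        "F": result.ymaze_anova.f_statistic,
        "p": result.ymaze_anova.p_value,
        "pairwise_vs_preop": {
            cond: {"t": t, "p": p} for cond, (t, p) in result.ymaze_anova.pairwise.items()
        },
    }
    (out_dir / "ymaze_anova.json").write_text(json.dumps(anova_payload, indent=2))
    (out_dir / "metadata.json").write_text(json.dumps(result.metadata, indent=2))

    geom = result.atlas.geometry
    write_labels(result.atlas.labels, geom, out_dir / "atlas.nii")
    for (seed_name, cond), vols in result.group_maps.items():
        import nibabel as nib

        img = nib.Nifti1Image(vols["t"].astype(np.float32), geom.affine)
        nib.save(img, str(out_dir / f"group_t_{seed_name}_{cond}.nii"))
        write_labels(
            vols["significant"].astype(np.int16), geom,
            out_dir / f"group_sig_{seed_name}_{cond}.nii",
        )

    for (region, cond), bundle in result.spectra.items():
        spec_l = bundle["spectrum_left"]
        spec_r = bundle["spectrum_right"]
        pd.DataFrame(
            {
                "frequency_hz": spec_l.frequencies,
                "amplitude_left": spec_l.amplitudes,
                "amplitude_right": spec_r.amplitudes,
            }
        ).to_csv(out_dir / f"spectrum_{region}_{cond}.csv", index=False, float_format="%.6g")
        pd.DataFrame(
            {"percent_left": bundle["left"], "percent_right": bundle["right"]}
        ).to_csv(out_dir / f"timecourse_{region}_{cond}.csv", index=False, float_format="%.6g")

    (out_dir / "log.txt").write_text("\n".join(result.log) + "\n")
    return out_dir
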