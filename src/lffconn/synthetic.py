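"""Synthetic longitudinal resting-state BOLD cohorts with known ground truth.

The generator emulates a longitudinal connectivity-loss-and-recovery design
in aged rats: bilateral primary somatosensory cortex (SI) and hippocampus
(Hp) share a band-limited low-frequency fluctuation (LFF, < 0.08 Hz);
postoperatively (days 1 and 3) the right-hemisphere members of both pairs
lose the shared signal, and by day 9 it is restored.  On top of the coupled
LFF each voxel receives independent white noise, a linear scanner drift,
globally phased physiological sinusoids (respiration ~1 Hz, cardiac ~5 Hz,
which alias under TR 2 s sampling), and a constant baseline.  Optionally one
rat's runs carry a large quadratic baseline drift, mimicking the kind of
acquisition artifact that forces a subject's exclusion.

Every run comes with a :class:`GroundTruth` record (coupling amplitudes,
drift, physiological phases, and the latent LFF series themselves), and the
whole cohort is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .io import BoldRun, VolumeGeometry, write_labels, write_manifest, write_run

__all__ = [
    "CONDITIONS",
    "REGIONS",
    "LABEL_IDS",
    "SyntheticConfig",
    "GroundTruth",
    "Atlas",
    "pocd_coupling",
    "make_atlas",
    "simulate_lff",
    "simulate_run",
    "simulate_cohort",
    "simulate_ymaze",
    "DEFAULT_YMAZE_MEANS",
    "DEFAULT_YMAZE_SDS",
]

#: Session conditions in longitudinal order: preoperative, postoperative
#: days 1, 3 and 9.
CONDITIONS = ("preop", "d1", "d3", "d9")

REGIONS = ("SI", "Hp")
HEMISPHERES = ("L", "R")

#: Integer labels of the toy atlas volume.
LABEL_IDS = {"background": 0, "SI_L": 1, "SI_R": 2, "Hp_L": 3, "Hp_R": 4}

#: Stereotaxic seed points (mm) for the left-hemisphere regions; right
#: regions are exact X-mirrors.
REGION_SEED_MM = {"SI": (-4.2, -2.2, -0.2), "Hp": (-4.8, -2.4, -0.4)}

#: In-plane field of view (x, y) and slab thickness (z) in mm, kept fixed
#: across grid resolutions so that reduced grids cover the same anatomy with
#: larger voxels.
FOV_MM = (50.0, 41.0, 20.0)


def pocd_coupling(
    amplitude: float = 1.2, day9_amplitude: float | None = None
) -> dict[tuple[str, str, str], float]:
    """Coupling map for the loss-and-recovery design.

    Left-hemisphere SI/Hp carry the shared LFF at ``amplitude`` (units of the
    noise SD) in every session; the right hemisphere carries it preop and on
    day 9 but amplitude 0 on days 1 and 3.  ``day9_amplitude`` defaults to the
    preoperative amplitude ("restored to normal").
    """
    if day9_amplitude is None:
        day9_amplitude = amplitude
    coupling: dict[tuple[str, str, str], float] = {}
    for region in REGIONS:
        for cond in CONDITIONS:
            coupling[(region, "L", cond)] = amplitude
            if cond in ("d1", "d3"):
                coupling[(region, "R", cond)] = 0.0
            elif cond == "d9":
                coupling[(region, "R", cond)] = day9_amplitude
            else:
                coupling[(region, "R", cond)] = amplitude
    return coupling


def _voxels_for_fov(grid_shape) -> tuple[float, float, float]:
    return tuple(f / s for f, s in zip(FOV_MM, grid_shape))


@dataclass
class SyntheticConfig:
    """Full generative parameterization of one rat-session BOLD run.

    Defaults reproduce the study's acquisition: 96x96 in-plane matrix over a
    50x41 mm field of view, 20 x 1 mm slices, 120 steady-state volumes at
    TR 2 s after 5 dummy scans, LFF band 0.01-0.08 Hz, coupling 1.2x the
    voxel noise SD, and respiration/cardiac sinusoids near 1 and 5 Hz.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 20)
    voxel_size_mm: tuple[float, float, float] | None = None
    n_volumes: int = 120
    n_dummy: int = 5
    tr_s: float = 2.0
    lff_band_hz: tuple[float, float] = (0.01, 0.08)
    coupling: dict[tuple[str, str, str], float] = field(default_factory=pocd_coupling)
    noise_sd: float = 1.0
    drift_slope_range: tuple[float, float] = (-0.01, 0.01)
    nonlinear_drift_amplitude: float = 5.0
    physio: tuple[tuple[float, float], ...] = ((1.2, 0.5), (4.9, 0.3))
    rng_seed: int = 0
    baseline: float = 100.0
    #: Grid centre in atlas mm; z = -0.3 puts the SI/Hp interface on a slice
    #: boundary at every supported resolution.
    grid_center_mm: tuple[float, float, float] = (0.0, 0.0, -0.3)
    #: Atlas region box extents in mm (10x10x3 voxels at full resolution).
    region_extent_mm: tuple[float, float, float] = (5.2, 4.3, 3.0)
    #: Fractional signal elevation of the first dummy frame (stylized
    #: pre-steady-state saturation, confined to the dummy frames).
    dummy_transient_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.voxel_size_mm is None:
            self.voxel_size_mm = _voxels_for_fov(self.grid_shape)
        if any(int(s) < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ParameterError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_volumes < 2:
            raise ParameterError("n_volumes must be >= 2")
        if self.n_dummy < 0:
            raise ParameterError("n_dummy must be >= 0")
        if self.tr_s <= 0:
            raise ParameterError("tr_s must be positive")
        low, high = self.lff_band_hz
        if not (0 <= low < high <= self.nyquist_hz + 1e-12):
            raise ParameterError(
                f"LFF band {self.lff_band_hz} must satisfy 0 <= low < high <= "
                f"Nyquist ({self.nyquist_hz:g} Hz)"
            )
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.nonlinear_drift_amplitude < 0:
            raise ParameterError("nonlinear_drift_amplitude must be >= 0")
        if any(a < 0 for _, a in self.physio):
            raise ParameterError("physio amplitudes must be >= 0")
        if any(a < 0 for a in self.coupling.values()):
            raise ParameterError("coupling amplitudes must be >= 0")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    @property
    def geometry(self) -> VolumeGeometry:
        origin = tuple(
            c - s * v / 2.0
            for c, s, v in zip(self.grid_center_mm, self.grid_shape, self.voxel_size_mm)
        )
        return VolumeGeometry(tuple(self.grid_shape), tuple(self.voxel_size_mm), origin)

    @classmethod
    def reduced(cls, grid_shape=(48, 48, 10), **kw) -> "SyntheticConfig":
        """Same anatomy/FOV on a coarser grid (cheaper cohorts)."""
        return cls(grid_shape=tuple(grid_shape), **kw)


@dataclass
class GroundTruth:
    """Everything the generator knew about one run."""

    rat_id: str
    condition: str
    coupling: dict[str, float]  # "SI_L" -> amplitude, ...
    drift_slope: float
    quad_amplitude: float  # 0 unless this run carries the outlier drift
    physio: list[tuple[float, float, float]]  # (freq Hz, amplitude, phase)
    is_outlier: bool
    latents: dict[str, np.ndarray] = field(default_factory=dict)  # region -> series

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["latents"] = {k: np.asarray(v).tolist() for k, v in self.latents.items()}
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["latents"] = {k: np.asarray(v) for k, v in payload["latents"].items()}
        payload["physio"] = [tuple(p) for p in payload["physio"]]
        return cls(**payload)


@dataclass
class Atlas:
    """Toy label volume: four rectangular regions on an axis-aligned grid."""

    labels: np.ndarray
    geometry: VolumeGeometry

    def mask(self, name: str) -> np.ndarray:
        if name not in LABEL_IDS:
            raise ParameterError(f"unknown region label {name!r}; know {sorted(LABEL_IDS)}")
        return self.labels == LABEL_IDS[name]

    def count(self, name: str) -> int:
        return int(self.mask(name).sum())

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(k for k in LABEL_IDS if k != "background")


def _region_box(
    region: str, geometry: VolumeGeometry, extent_mm
) -> tuple[range, range, range]:
    """Index ranges of the *left* box for one region.

    In-plane the box is centred on the seed point.  Along Z the cortex box
    extends dorsally from the seed slice and the hippocampus box ventrally,
    so the two stay disjoint even though their seed points are < 1 mm apart.
    """
    seed = REGION_SEED_MM[region]
    nvox = [max(1, round(e / v)) for e, v in zip(extent_mm, geometry.voxel_size_mm)]
    cx = (seed[0] - geometry.origin_mm[0]) / geometry.voxel_size_mm[0]
    cy = (seed[1] - geometry.origin_mm[1]) / geometry.voxel_size_mm[1]
    x0 = round(cx - nvox[0] / 2.0)
    y0 = round(cy - nvox[1] / 2.0)
    vz = geometry.mm_to_voxel(seed)[2]
    if region == "SI":
        zr = range(vz, vz + nvox[2])
    else:
        zr = range(vz - nvox[2] + 1, vz + 1)
    return range(x0, x0 + nvox[0]), range(y0, y0 + nvox[1]), zr


def make_atlas(
    grid_shape,
    voxel_size_mm=None,
    grid_center_mm=(0.0, 0.0, -0.3),
    region_extent_mm=(5.2, 4.3, 3.0),
) -> Atlas:
    """Build the four-region toy atlas (left/right SI, left/right Hp).

    Left boxes contain their stereotaxic seed points; right boxes are exact
    voxel mirror images across the X midline (the grid is centred at x = 0,
    so the midline is a voxel boundary).  Raises :class:`GeometryError`
    naming the offending region if a box falls outside the grid, misses its
    seed point, or overlaps another region.
    """
    if voxel_size_mm is None:
        voxel_size_mm = _voxels_for_fov(grid_shape)
    origin = tuple(
        c - s * v / 2.0 for c, s, v in zip(grid_center_mm, grid_shape, voxel_size_mm)
    )
    geometry = VolumeGeometry(tuple(int(s) for s in grid_shape), tuple(voxel_size_mm), origin)
    labels = np.zeros(geometry.shape, dtype=np.int16)
    nx = geometry.shape[0]
    occupied: dict[str, set] = {}
    for region in REGIONS:
        xr, yr, zr = _region_box(region, geometry, region_extent_mm)
        left = {(x, y, z) for x in xr for y in yr for z in zr}
        right = {(nx - 1 - x, y, z) for (x, y, z) in left}
        for hemi, vox in (("L", left), ("R", right)):
            name = f"{region}_{hemi}"
            for ijk in vox:
                if not geometry.contains_index(ijk):
                    raise GeometryError(
                        f"region {name} does not fit the grid (voxel {ijk} outside "
                        f"shape {geometry.shape})"
                    )
            for other, ovox in occupied.items():
                if vox & ovox:
                    raise GeometryError(f"regions {name} and {other} overlap")
            occupied[name] = vox
        seed_vox = geometry.mm_to_voxel(REGION_SEED_MM[region])
        if seed_vox not in occupied[f"{region}_L"]:
            raise GeometryError(
                f"region {region}_L does not contain its seed point "
                f"{REGION_SEED_MM[region]} mm (voxel {seed_vox})"
            )
    for name, vox in occupied.items():
        idx = np.array(sorted(vox))
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = LABEL_IDS[name]
    return Atlas(labels=labels, geometry=geometry)


def simulate_lff(
    n_volumes: int, tr_s: float, band_hz: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """One band-limited Gaussian LFF series, exactly zero mean and unit SD.

    White Gaussian noise is projected onto the Fourier bins inside
    ``band_hz`` (inclusive) and standardized; the discrete amplitude
    spectrum outside the band is identically zero.
    """
    if n_volumes < 4:
        raise ParameterError("need at least 4 volumes to synthesize an LFF series")
    nyquist = 1.0 / (2.0 * tr_s)
    low, high = band_hz
    if not (0 <= low < high):
        raise ParameterError(f"band {band_hz} must satisfy 0 <= low < high")
    if high > nyquist + 1e-12:
        raise ParameterError(f"band upper edge {high} Hz exceeds Nyquist {nyquist:g} Hz")
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ParameterError(
            f"band {band_hz} contains no nonzero Fourier bin at n={n_volumes}, TR={tr_s}"
        )
    spectrum = np.fft.rfft(rng.standard_normal(n_volumes))
    spectrum[~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_volumes)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ParameterError("degenerate LFF realization (zero variance)")
    return x / sd


def simulate_run(
    config: SyntheticConfig,
    condition: str,
    rng: np.random.Generator,
    rat_id: str = "rat01",
    outlier: bool = False,
) -> tuple[BoldRun, GroundTruth]:
    """Generate one rat-session 4D run plus its ground truth.

    Voxel model (dummy + steady-state frames alike)::

        s(v, t) = baseline + noise_sd * eps(v, t)
                  + a(region(v), hemi(v), condition) * L_region(t)
                  + slope * (t - T/2) + sum_k A_k cos(2 pi f_k t TR + phi_k)
                  [+ quad outlier drift]

    with one latent ``L_region`` per region shared by both hemispheres.
    Physio frequencies above Nyquist alias naturally because the cosine is
    evaluated at the sampling times.  Dummy frames additionally carry a
    decaying saturation transient.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}; know {CONDITIONS}")
    atlas = make_atlas(
        config.grid_shape,
        config.voxel_size_mm,
        config.grid_center_mm,
        config.region_extent_mm,
    )
    T = config.n_dummy + config.n_volumes
    t_idx = np.arange(T, dtype=float)
    t_centered = t_idx - (T - 1) / 2.0
    t_s = t_idx * config.tr_s

    latents = {
        region: simulate_lff(T, config.tr_s, config.lff_band_hz, rng) for region in REGIONS
    }
    data = rng.standard_normal(tuple(config.grid_shape) + (T,)) * config.noise_sd

    coupling_record: dict[str, float] = {}
    for region in REGIONS:
        for hemi in HEMISPHERES:
            a = float(config.coupling.get((region, hemi, condition), 0.0))
            coupling_record[f"{region}_{hemi}"] = a
            if a > 0:
                data[atlas.mask(f"{region}_{hemi}")] += a * latents[region]

    slope = float(rng.uniform(*config.drift_slope_range))
    global_tc = slope * t_centered
    physio_record: list[tuple[float, float, float]] = []
    for freq, amp in config.physio:
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        physio_record.append((float(freq), float(amp), phase))
        global_tc = global_tc + amp * np.cos(2.0 * np.pi * freq * t_s + phase)
    quad_amp = float(config.nonlinear_drift_amplitude) if outlier else 0.0
    if quad_amp:
        half = (T - 1) / 2.0
        global_tc = global_tc + quad_amp * (t_centered / half) ** 2
    data += global_tc + config.baseline
    if config.n_dummy:
        k = np.arange(config.n_dummy, dtype=float)
        data[..., : config.n_dummy] += (
            config.baseline * config.dummy_transient_frac * np.exp(-k / 1.5)
        )

    run = BoldRun(
        data=data.astype(np.float32),
        voxel_size_mm=tuple(config.voxel_size_mm),
        origin_mm=atlas.geometry.origin_mm,
        tr_s=config.tr_s,
        n_dummy=config.n_dummy,
        rat_id=rat_id,
        condition=condition,
    )
    truth = GroundTruth(
        rat_id=rat_id,
        condition=condition,
        coupling=coupling_record,
        drift_slope=slope,
        quad_amplitude=quad_amp,
        physio=physio_record,
        is_outlier=bool(outlier),
        latents={k: v.copy() for k, v in latents.items()},
    )
    return run, truth


def simulate_cohort(
    config: SyntheticConfig,
    n_rats: int,
    out_dir,
    include_drift_outlier: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_rats`` x 4 sessions, write volumes + sidecars + manifest.

    One rat (chosen reproducibly from the seed) receives the quadratic
    baseline drift in all of its runs when ``include_drift_outlier`` is set.
    Returns the manifest; identical ``(config, seed)`` give byte-identical
    outputs.  Existing run files raise :class:`FileExistsError`.
    """
    if n_rats < 1:
        raise ParameterError("n_rats must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(n_rats * len(CONDITIONS) + 1)
    pick_rng = np.random.default_rng(children[0])
    outlier_rat = int(pick_rng.integers(n_rats)) if include_drift_outlier else -1

    atlas = make_atlas(
        config.grid_shape, config.voxel_size_mm, config.grid_center_mm, config.region_extent_mm
    )
    write_labels(atlas.labels, atlas.geometry, out_dir / "atlas.nii")

    rows = []
    k = 1
    for i in range(n_rats):
        rat_id = f"rat{i + 1:02d}"
        for condition in CONDITIONS:
            rng = np.random.default_rng(children[k])
            k += 1
            is_outlier = i == outlier_rat
            run, truth = simulate_run(config, condition, rng, rat_id, outlier=is_outlier)
            run_path = out_dir / f"{rat_id}_{condition}.nii"
            gt_path = out_dir / f"{rat_id}_{condition}_truth.json"
            if run_path.exists():
                raise FileExistsError(f"refusing to overwrite existing run {run_path}")
            write_run(run, run_path)
            truth.to_json(gt_path)
            rows.append(
                {
                    "rat_id": rat_id,
                    "condition": condition,
                    "path": str(run_path),
                    "is_outlier": is_outlier,
                    "n_dummy": config.n_dummy,
                    "groundtruth_path": str(gt_path),
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


#: Trials-to-criterion means/SDs per session: the printed preop and day-1/3
#: values; day 9 is not printed (only "not significantly different from
#: preoperative", p ~ 0.4) and is set to a statistically indistinguishable
#: 29 +/- 6.
DEFAULT_YMAZE_MEANS = {"preop": 27.0, "d1": 77.0, "d3": 70.0, "d9": 29.0}
DEFAULT_YMAZE_SDS = {"preop": 5.0, "d1": 18.0, "d3": 14.0, "d9": 6.0}


def simulate_ymaze(
    n_rats: int,
    condition_means: dict[str, float] | None = None,
    condition_sds: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Y-maze trials-to-criterion per rat per session.

    Counts are drawn per condition from a normal at the given mean/SD,
    rounded to integers and truncated at 1 (a rat needs at least one trial).
    """
    means = dict(DEFAULT_YMAZE_MEANS if condition_means is None else condition_means)
    sds = dict(DEFAULT_YMAZE_SDS if condition_sds is None else condition_sds)
    if set(means) != set(sds):
        raise ParameterError("means and sds must cover the same conditions")
    if any(m < 1 for m in means.values()):
        raise ParameterError("Y-maze means must be >= 1")
    if any(s < 0 for s in sds.values()):
        raise ParameterError("Y-maze SDs must be >= 0")
    if n_rats < 1:
        raise ParameterError("n_rats must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for cond in means:
        draws = rng.normal(means[cond], sds[cond], size=n_rats)
        counts = np.maximum(1, np.rint(draws).astype(int))
        for i, c in enumerate(counts):
            rows.append(
                {"rat_id": f"rat{i + 1:02d}", "condition": cond, "trials_to_criterion": int(c)}
            )
    return pd.DataFrame(rows)
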