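"""End-to-end experiment recipes at desk scale.

These routines wire phantom -> probe -> scan -> dose -> detector ->
reconstruction -> metrics into the studies the package is built for:
parameter recovery at high dose, resolution versus dose, probe-design
comparison, and the averaging of independent low-dose datasets.  They run
on a reduced geometry (32-pixel detector, 64-pixel objects by default) so
each study completes in seconds to minutes on one CPU; the probe
parameters keep the published optics (400 nm defocused beam, zone plate,
random phase plate) at a 4.5 mrad aperture that fits the reduced
detector's angular range.

Two conventions apply throughout the recipes (see docs/methods.md):

* evaluation metrics are computed on the central half of the object,
  where the scan illuminates every pixel well — the border of a
  ptychographic field of view is only weakly constrained by the data;
* the gradient-truncation rule is disabled (alpha_h = inf) in the study
  configurations: with strongly peaked diffraction patterns its
  amplitude-proportional bound permanently discards dark-field
  measurements and stalls the solver at these problem sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .detector import DetectorResponse, apply_detector, dose_summary, scale_to_dose
from .forward import ForwardOperator, ObjectField, forward_apply
from .geometry import ComplexField2D, ExperimentGeometry, geometry_for_pixel_size, raster_scan
from .metrics import (
    align_global_scale,
    average_reconstructions,
    frc,
    nrmse,
    resolution_from_frc,
    snr_db,
)
from .phantom import PhantomSpec, generate_phantom
from .probes import (
    ProbeField,
    make_defocused_probe,
    make_fzp_probe,
    make_random_probe,
    step_from_overlap,
)
from .reconstruct import ReconConfig, reconstruct

__all__ = [
    "small_geometry",
    "small_phantom",
    "build_probe",
    "jittered_raster",
    "simulate_counts",
    "run_reconstruction",
    "study_recon_config",
    "central_crop",
    "phase_image",
    "recovery_experiment",
    "dose_resolution_experiment",
    "probe_comparison",
    "averaging_experiment",
    "averaging_trend",
]

_SMALL_DETECTOR = 32
_SMALL_HALF_ANGLE = 4.5  # mrad, within the reduced detector's Nyquist angle


def study_recon_config(**overrides) -> ReconConfig:
    """Solver configuration used by the study recipes: sparse prior with
    the wavelet denoiser, truncation disabled, 200 CG iterations."""
    base = dict(
        prior="sparse", alpha_h=np.inf, max_iters=200, rel_tol=1e-10
    )
    base.update(overrides)
    return ReconConfig(**base)


def small_geometry(
    n_detector_pixels: int = _SMALL_DETECTOR, pixel_size: float = 1.7
) -> ExperimentGeometry:
    return geometry_for_pixel_size(
        pixel_size,
        n_detector_pixels=n_detector_pixels,
        probe_half_angle=_SMALL_HALF_ANGLE,
    )


def small_phantom(object_size: int = 64, seed: int = 0) -> ObjectField:
    spec = PhantomSpec(
        grid=(object_size, object_size),
        pixel_size=1.7,
        n_pseudo_atoms=max(10, object_size // 2),
        seed=seed,
    )
    return generate_phantom(spec)[0]


def build_probe(
    kind: str, geom: ExperimentGeometry, seed: int = 0, electrons: float = 1.0
) -> ProbeField:
    """The three benchmark illuminations on the reduced geometry: 400 nm
    defocused, zone plate 300 nm from focus, randomized phase plate."""
    if kind == "defocused":
        return make_defocused_probe(geom, 400.0, geom.probe_half_angle, electrons)
    if kind == "fzp":
        return make_fzp_probe(geom, 300.0, electrons)
    if kind == "random":
        return make_random_probe(geom, 2.0, seed, electrons)
    raise ValueError(f"unknown probe kind {kind!r}")


def jittered_raster(
    object_shape: tuple[int, int],
    patch_shape: tuple[int, int],
    step: int,
    rng: np.random.Generator,
    overlap: float = 0.0,
):
    """Raster scan with a random origin and per-position jitter.

    A strictly periodic raster imprints an artifact at the scan frequency
    that is shared between independent datasets and so survives
    averaging; randomizing the grid per dataset decorrelates it.  Jitter
    is +/- step/3 pixels, positions are clipped to the valid range and
    deduplicated.
    """
    from .geometry import ScanPlan

    jitter = max(1, step // 3)
    oy, ox = rng.integers(0, step, size=2)
    rows = np.arange(oy, object_shape[0] - patch_shape[0] + 1, step)
    cols = np.arange(ox, object_shape[1] - patch_shape[1] + 1, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pos = np.stack([rr.ravel(), cc.ravel()], axis=1)
    pos = pos + rng.integers(-jitter, jitter + 1, size=pos.shape)
    pos[:, 0] = np.clip(pos[:, 0], 0, object_shape[0] - patch_shape[0])
    pos[:, 1] = np.clip(pos[:, 1], 0, object_shape[1] - patch_shape[1])
    pos = np.unique(pos, axis=0)
    return ScanPlan(positions=pos, step=int(step), overlap_fraction=overlap)


def simulate_counts(
    truth: ObjectField,
    probe: ProbeField,
    geom: ExperimentGeometry,
    dose: float,
    detector_seed: int,
    overlap: float = 0.75,
    response: DetectorResponse | None = None,
    jitter_scan: bool = True,
):
    """Scan plan from the overlap rule, dose-calibrated counts, operator.

    By default the raster is randomized (origin + jitter, seeded from
    ``detector_seed``) to avoid raster-grid artifacts; pass
    ``jitter_scan=False`` for a strictly periodic scan.  The returned
    operator carries the probe rescaled to the dose-calibrated electron
    budget, so model intensities for |T| ~ 1 live on the same scale as
    the counts.
    """

    from .geometry import ComplexField2D
    from .probes import ProbeField

    step = step_from_overlap(probe, overlap)
    if jitter_scan:
        rng = np.random.default_rng(np.random.SeedSequence([detector_seed, 977]))
        scan = jittered_raster(truth.shape, probe.field.shape, step, rng, overlap)
    else:
        scan = raster_scan(truth.shape, probe.field.shape, step, overlap)
    operator = ForwardOperator(probe=probe, scanplan=scan, object_shape=truth.shape)
    noise_free = forward_apply(truth, operator)
    calibrated = scale_to_dose(noise_free, dose, scan, geom)
    counts = apply_detector(
        calibrated, response or DetectorResponse.identity(), detector_seed
    )
    # Rescale the probe so that sum_i |psi|^2 matches the calibrated mean
    # electrons per pattern (the same factor scale_to_dose applied).
    mean_sum = noise_free.pattern_sums().mean()
    target = calibrated.electrons_per_pattern or 0.0
    if mean_sum > 0 and target > 0:
        factor = np.sqrt(target / mean_sum)
        scaled_probe = ProbeField(
            field=ComplexField2D(probe.values * factor, probe.pixel_size),
            total_electrons=probe.total_electrons * factor**2,
            aperture_half_angle=probe.aperture_half_angle,
        )
        operator = ForwardOperator(
            probe=scaled_probe, scanplan=scan, object_shape=truth.shape
        )
    return counts, operator, scan


def run_reconstruction(
    counts,
    operator: ForwardOperator,
    config: ReconConfig | None = None,
    n_starts: int = 1,
    pilot_iters: int = 30,
    **overrides,
):
    """Reconstruct, optionally with multi-start.

    The MAP objective is non-convex and a random start occasionally
    converges to a poor stationary point; with ``n_starts > 1`` the run
    is repeated from distinct init seeds and the lowest final objective
    wins.  (``pilot_iters`` is kept for API stability but full runs are
    raced: early objective values do not discriminate between basins.)
    """
    config = config or study_recon_config()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    if n_starts <= 1:
        return reconstruct(counts.data, operator, config)
    runs = []
    for k in range(n_starts):
        cfg_k = dataclasses.replace(config, seed=config.seed + 7919 * k)
        runs.append(reconstruct(counts.data, operator, cfg_k))
    return min(runs, key=lambda s: s.objective_trace[-1])


def central_crop(values: np.ndarray) -> np.ndarray:
    """Central half of the field (the well-illuminated interior)."""
    n1, n2 = values.shape
    return values[n1 // 4 : n1 - n1 // 4, n2 // 4 : n2 - n2 // 4]


def phase_image(values: np.ndarray, pixel_size: float) -> ComplexField2D:
    """Phase of a complex field as a real image carrier for FRC/SNR."""
    return ComplexField2D(np.angle(values) + 0j, pixel_size)


def _aligned_phase_pair(truth: ObjectField, recon_values: np.ndarray):
    aligned = align_global_scale(truth.values, recon_values)
    px = truth.pixel_size
    return (
        phase_image(central_crop(truth.values), px),
        phase_image(central_crop(aligned), px),
    )


def recovery_experiment(
    dose: float = 1000.0,
    seed: int = 0,
    object_size: int = 64,
    max_iters: int = 200,
    probe_kind: str = "random",
    prior: str = "none",
    phantom_seed: int = 0,
) -> dict:
    """High-dose parameter recovery: NRMSE of the reconstruction against
    the phantom transmission over the well-illuminated interior.

    The specimen (``phantom_seed``) is a fixed study condition; ``seed``
    drives the run's randomness (probe, detector, initialization)."""
    geom = small_geometry()
    truth = small_phantom(object_size, seed=phantom_seed)
    probe = build_probe(probe_kind, geom, seed=seed + 1)
    counts, operator, scan = simulate_counts(truth, probe, geom, dose, seed + 2)
    state = run_reconstruction(
        counts,
        operator,
        study_recon_config(prior=prior, max_iters=max_iters, seed=seed + 3),
    )
    px = truth.pixel_size
    err = nrmse(
        ComplexField2D(central_crop(truth.values), px),
        ComplexField2D(central_crop(state.current.values), px),
    )
    return {
        "nrmse": err,
        "iterations": state.iterations,
        "state": state,
        "truth": truth,
        "n_patterns": scan.n_positions,
        "dose_summary": dose_summary(dose, scan.step, geom),
    }


def _reconstruct_once(
    truth: ObjectField,
    geom: ExperimentGeometry,
    dose: float,
    seed: int,
    probe_kind: str = "random",
    max_iters: int = 200,
    jitter_scan: bool = True,
):
    probe = build_probe(probe_kind, geom, seed=seed)
    counts, operator, _ = simulate_counts(
        truth, probe, geom, dose, seed + 1, jitter_scan=jitter_scan
    )
    return run_reconstruction(
        counts,
        operator,
        study_recon_config(max_iters=max_iters, seed=seed + 2),
        n_starts=3,
    )


def dose_resolution_experiment(
    doses: tuple[float, ...] = (5.0, 20.0, 80.0),
    n_seeds: int = 5,
    object_size: int = 96,
    max_iters: int = 200,
    seed: int = 0,
    phantom_seed: int = 0,
) -> dict[float, float]:
    """Median 1/2-bit FRC resolution (A, phase against the phantom phase)
    per dose on one fixed phantom; resolution improves (decreases in A)
    with dose.  The phantom is a fixed study condition; ``seed`` drives
    the per-dataset randomness."""
    geom = small_geometry()
    truth = small_phantom(object_size, seed=phantom_seed)
    out: dict[float, float] = {}
    for dose in doses:
        resolutions = []
        for k in range(n_seeds):
            state = _reconstruct_once(
                truth, geom, dose, seed=1000 * k + int(dose) + seed,
                max_iters=max_iters,
            )
            pt, pr = _aligned_phase_pair(truth, state.current.values)
            res, _ = resolution_from_frc(frc(pt, pr), "half_bit")
            resolutions.append(res)
        out[dose] = float(np.median(resolutions))
    return out


def probe_comparison(
    dose: float = 20.0,
    seed: int = 0,
    object_size: int = 64,
    max_iters: int = 200,
    phantom_seed: int = 0,
    n_seeds: int = 3,
) -> dict[str, dict[str, float]]:
    """Low-spatial-frequency SNR (mean over the lowest quartile of rings,
    DC excluded) of phase reconstructions with the three probe designs,
    median over ``n_seeds`` independent datasets per probe.

    Runs on a strictly periodic raster: the defocused probe's deficit is
    its low data diversity between neighbouring positions, which scan
    jittering would partly mask."""
    geom = small_geometry()
    truth = small_phantom(object_size, seed=phantom_seed)
    results: dict[str, dict[str, float]] = {}
    for kind in ("defocused", "fzp", "random"):
        lows, errs = [], []
        for k in range(n_seeds):
            state = _reconstruct_once(
                truth, geom, dose, seed=seed + 17 + 1009 * k, probe_kind=kind,
                max_iters=max_iters, jitter_scan=False,
            )
            pt, pr = _aligned_phase_pair(truth, state.current.values)
            curve = snr_db(pt, pr)
            n_low = max(2, len(curve.snr_db) // 4)
            lows.append(float(np.mean(curve.snr_db[1 : n_low + 1])))
            errs.append(nrmse(pt, pr))
        results[kind] = {
            "low_freq_snr_db": float(np.median(lows)),
            "nrmse": float(np.median(errs)),
        }
    return results


def averaging_experiment(
    n_datasets: int = 30,
    dose: float = 20.0,
    object_size: int = 64,
    max_iters: int = 100,
    seed: int = 0,
    phantom_seed: int = 0,
) -> dict:
    """Reconstruct ``n_datasets`` independent datasets of one phantom,
    average with global-phase alignment, and report the split-half 1/2-bit
    FRC resolution of the interior."""
    geom = small_geometry()
    truth = small_phantom(object_size, seed=phantom_seed)
    fields = []
    px = truth.pixel_size
    for k in range(n_datasets):
        state = _reconstruct_once(
            truth, geom, dose, seed=seed + 37 * (k + 1), max_iters=max_iters
        )
        aligned = align_global_scale(truth.values, state.current.values)
        fields.append(ComplexField2D(central_crop(aligned), px))
    mean, curve = average_reconstructions(fields)
    res, crossed = resolution_from_frc(curve, "half_bit")
    return {
        "split_half_resolution_A": res,
        "crossed": crossed,
        "average": mean,
        "fields": fields,
        "nrmse_of_average": nrmse(
            ComplexField2D(central_crop(truth.values), px), mean
        ),
        "truth": truth,
    }


def averaging_trend(
    n_small: int = 6,
    n_large: int = 30,
    n_replicates: int = 3,
    dose: float = 20.0,
    object_size: int = 64,
    max_iters: int = 100,
    seed: int = 0,
) -> dict:
    """Split-half FRC resolution of ``n_small``- versus ``n_large``-fold
    averages, median over replicates.  Pooling more independent low-dose
    reconstructions should improve (lower) the split-half resolution."""
    res_small, res_large = [], []
    for rep in range(n_replicates):
        pool = averaging_experiment(
            n_datasets=n_large,
            dose=dose,
            object_size=object_size,
            max_iters=max_iters,
            seed=seed + 10_000 * rep,
        )
        fields = pool["fields"]
        _, curve_small = average_reconstructions(fields[:n_small])
        res_s, _ = resolution_from_frc(curve_small, "half_bit")
        res_small.append(res_s)
        res_large.append(pool["split_half_resolution_A"])
    return {
        "median_resolution_small_A": float(np.median(res_small)),
        "median_resolution_large_A": float(np.median(res_large)),
        "n_small": n_small,
        "n_large": n_large,
    }
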