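"""Run configuration and the HDF5 dataset container.

One self-describing HDF5 file ties the pipeline stages together:

    /entry/data        (K, m, m) detected counts
    /entry/probe       (m, m) complex probe at the specimen plane
    /entry/positions   (K, 2) integer top-left patch offsets
    /ground_truth/transmission   (n, n) complex phantom (simulation only)
    /simulation/noise_free       optional noise-free stack

plus all parameters as root attributes (geometry and configuration as a
JSON string), so any output can be regenerated from its own metadata.
Seed policy: a master seed spawns named substreams (phantom, probe,
detector, init) so every random choice is traceable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .detector import (
    DetectorResponse,
    DiffractionStack,
    apply_detector,
    dose_summary,
    scale_to_dose,
)
from .forward import ForwardOperator, ObjectField, forward_apply
from .geometry import (
    ComplexField2D,
    ExperimentGeometry,
    ScanPlan,
    geometry_for_pixel_size,
    raster_scan,
)
from .phantom import PhantomSpec, generate_phantom
from .probes import ProbeField, ProbeSpec, step_from_overlap
from .reconstruct import ReconConfig

__all__ = [
    "RunConfig",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "substream_seed",
]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic named substream below 2^31."""
    h = np.random.SeedSequence(
        [master_seed, int.from_bytes(name.encode(), "little") % (2**31)]
    )
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to simulate and reconstruct one dataset."""

    # Note: at r_d = 1.7 A the detector's angular Nyquist limit is 5.8 mrad,
    # so the default aperture is 4.5 mrad; a 9.2 mrad aperture needs a finer
    # pixel size (see docs/methods.md on the geometry inference).
    pixel_size: float = 1.7  # A
    n_detector_pixels: int = 128
    electron_energy: float = 300.0
    probe_half_angle: float = 4.5  # mrad
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    overlap: float = 0.75
    dose: float = 20.0  # e-/A^2
    object_size: int = 256
    phantom: PhantomSpec | None = None
    detector: str = "identity"  # {"identity", "k2"}
    recon: ReconConfig = field(default_factory=ReconConfig)
    master_seed: int = 0

    def geometry(self) -> ExperimentGeometry:
        return geometry_for_pixel_size(
            self.pixel_size,
            electron_energy=self.electron_energy,
            n_detector_pixels=self.n_detector_pixels,
            probe_half_angle=self.probe_half_angle,
        )

    def response(self) -> DetectorResponse:
        if self.detector == "identity":
            return DetectorResponse.identity()
        if self.detector == "k2":
            return DetectorResponse.k2_like()
        raise ValueError(f"unknown detector response {self.detector!r}")

    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=encode, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if raw.get("probe"):
            raw["probe"] = ProbeSpec(**raw["probe"])
        if raw.get("phantom"):
            ph = raw["phantom"]
            ph["grid"] = tuple(ph["grid"])
            raw["phantom"] = PhantomSpec(**ph)
        if raw.get("recon"):
            raw["recon"] = ReconConfig(**raw["recon"])
        return cls(**raw)


@dataclass
class SimulatedDataset:
    counts: DiffractionStack
    noise_free: DiffractionStack
    probe: ProbeField
    scanplan: ScanPlan
    geometry: ExperimentGeometry
    ground_truth: ObjectField
    config: RunConfig
    summary: dict[str, float]


def simulate_dataset(config: RunConfig) -> SimulatedDataset:
    """Phantom -> probe -> scan -> noise-free stack -> dose -> detector."""
    geom = config.geometry()
    phantom_spec = config.phantom or PhantomSpec(
        grid=(config.object_size, config.object_size),
        pixel_size=config.pixel_size,
        seed=substream_seed(config.master_seed, "phantom"),
    )
    truth, _ = generate_phantom(phantom_spec)

    probe_spec = dataclasses.replace(
        config.probe, seed=substream_seed(config.master_seed, "probe")
    )
    probe = probe_spec.build(geom, electrons=1.0)
    step = step_from_overlap(probe, config.overlap)
    scan = raster_scan(
        truth.shape, probe.field.shape, step, overlap_fraction=config.overlap
    )
    operator = ForwardOperator(
        probe=probe, scanplan=scan, object_shape=truth.shape
    )
    noise_free = forward_apply(truth, operator)
    calibrated = scale_to_dose(noise_free, config.dose, scan, geom)
    counts = apply_detector(
        calibrated, config.response(), substream_seed(config.master_seed, "detector")
    )
    return SimulatedDataset(
        counts=counts,
        noise_free=calibrated,
        probe=probe,
        scanplan=scan,
        geometry=geom,
        ground_truth=truth,
        config=config,
        summary=dose_summary(config.dose, step, geom),
    )


def write_dataset(path, sim: SimulatedDataset, store_noise_free: bool = False) -> None:
    with h5py.File(path, "w") as fh:
        entry = fh.create_group("entry")
        entry.create_dataset("data", data=sim.counts.data)
        entry.create_dataset("probe", data=sim.probe.values)
        entry.create_dataset("positions", data=sim.scanplan.positions)
        gt = fh.create_group("ground_truth")
        gt.create_dataset("transmission", data=sim.ground_truth.values)
        if store_noise_free:
            fh.create_group("simulation").create_dataset(
                "noise_free", data=sim.noise_free.data
            )
        fh.attrs["config_json"] = sim.config.to_json()
        fh.attrs["pixel_size"] = sim.geometry.image_pixel_size
        fh.attrs["dose"] = sim.counts.dose if sim.counts.dose is not None else -1.0
        fh.attrs["electrons_per_pattern"] = sim.counts.electrons_per_pattern or 0.0
        fh.attrs["scan_step"] = sim.scanplan.step
        fh.attrs["probe_total_electrons"] = sim.probe.total_electrons
        fh.attrs["probe_half_angle"] = sim.probe.aperture_half_angle
        for key, value in sim.summary.items():
            fh.attrs[key] = value


def read_dataset(path):
    """Counts, probe, scan plan, geometry, ground truth and config from an
    HDF5 container.  Missing groups raise a schema error naming the path."""
    with h5py.File(path, "r") as fh:
        for required in ("entry/data", "entry/probe", "entry/positions"):
            if required not in fh:
                raise KeyError(f"dataset is missing required group '/{required}'")
        config = RunConfig.from_json(fh.attrs["config_json"])
        geom = config.geometry()
        counts = DiffractionStack(
            data=fh["entry/data"][...],
            dose=float(fh.attrs["dose"]) if fh.attrs["dose"] >= 0 else None,
            electrons_per_pattern=float(fh.attrs["electrons_per_pattern"]),
        )
        probe = ProbeField(
            field=ComplexField2D(fh["entry/probe"][...], float(fh.attrs["pixel_size"])),
            total_electrons=float(fh.attrs["probe_total_electrons"]),
            aperture_half_angle=float(fh.attrs["probe_half_angle"]),
        )
        scan = ScanPlan(
            positions=fh["entry/positions"][...],
            step=int(fh.attrs["scan_step"]),
            overlap_fraction=config.overlap,
        )
        truth = None
        if "ground_truth/transmission" in fh:
            truth = ObjectField(
                ComplexField2D(
                    fh["ground_truth/transmission"][...],
                    float(fh.attrs["pixel_size"]),
                )
            )
    return counts, probe, scan, geom, truth, config
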