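"""End-to-end low-dose run: phantom -> diffraction counts -> MAP recovery.

Simulates a 64^2 macromolecule-in-ice phantom scanned with a randomized
probe at 20 e-/A^2, reconstructs with the Poisson MAP solver (sparse
wavelet prior), and evaluates interior NRMSE and FRC resolution against
the ground-truth phase.
"""

from cryoptycho.geometry import ComplexField2D
from cryoptycho.metrics import (
    align_global_scale,
    frc,
    nrmse,
    resolution_from_frc,
)
from cryoptycho.workflows import (
    build_probe,
    central_crop,
    phase_image,
    run_reconstruction,
    simulate_counts,
    small_geometry,
    small_phantom,
)

geom = small_geometry()
truth = small_phantom(96, seed=0)
probe = build_probe("random", geom, seed=1)
counts, operator, scan = simulate_counts(truth, probe, geom, dose=20.0,
                                         detector_seed=2)
print(f"simulated {scan.n_positions} patterns, "
      f"mean {counts.data.mean():.2f} counts per detector pixel")

state = run_reconstruction(counts, operator, seed=3, n_starts=3)
print(f"solver finished after {state.iterations} iterations "
      f"(converged={state.converged})")

aligned = align_global_scale(truth.values, state.current.values)
px = truth.pixel_size
interior_truth = ComplexField2D(central_crop(truth.values), px)
interior_recon = ComplexField2D(central_crop(aligned), px)
err = nrmse(interior_truth, interior_recon)
curve = frc(phase_image(central_crop(truth.values), px),
            phase_image(central_crop(aligned), px))
res, crossed = resolution_from_frc(curve, "half_bit")
print(f"interior NRMSE               : {err:.3f}")
print(f"1/2-bit FRC resolution       : {res:.1f} A (crossed={crossed})")
# At 20 e-/A^2 a single dataset typically resolves ~4-6 A on this phantom;
# the NRMSE is dominated by the weak amplitude contrast, the FRC by how far
# the recovered phase tracks the true projected potential.
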