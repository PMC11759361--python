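"""Seeded simulation studies that validate the pipeline end to end.

Each study generates synthetic data with known ground truth, runs the full
pipeline, and reports recovery metrics.  They are used by the test suite
and by ``scripts/acceptance.py``; problem sizes are the package's standard
validation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mechanics, stats, synthetic, wrapping

# the three artificial-axon materials, stiffest to softest (Pa)
MATERIAL_MODULI = {"X": 13000.0, "Y": 780.0, "Z": 98.0}


@dataclass
class SweepResult:
    """Per-pillar classification outcomes of the decision-boundary sweep."""

    n_pillars: int
    n_correct: int
    cells_wrapped: dict[tuple[float, float], int]  # (coverage, span_um) -> wrapped count
    cells_total: dict[tuple[float, float], int]

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_pillars


def decision_boundary_sweep(
    coverages: tuple[float, ...] = (0.5, 0.7, 0.85, 1.0),
    spans_um: tuple[float, ...] = (2.0, 4.0, 8.0),
    seeds_per_cell: int = 20,
    noise: bool = True,
    seed0: int = 0,
) -> SweepResult:
    """Sweep angular coverage x contiguous span on 3x3 grids.

    All nine pillars of a field share one (coverage, span) cell; the sheath
    start slice and angular offset vary per pillar.  Under the >80% / >6 µm
    rule only the (coverage > 0.8) x (span > 6 µm) cells contain wrapped
    pillars.  Returns per-pillar classification accuracy against ground
    truth and the wrapped counts per cell.
    """
    n_slices, z_step = 8, 2.0
    n_correct = n_total = 0
    cells_wrapped: dict[tuple[float, float], int] = {}
    cells_total: dict[tuple[float, float], int] = {}
    params = wrapping.QuantParams()
    for ci, cov in enumerate(coverages):
        for si, span in enumerate(spans_um):
            span_slices = int(round(span / z_step))
            key = (cov, span)
            cells_wrapped[key] = 0
            cells_total[key] = 0
            for rep in range(seeds_per_cell):
                seed = seed0 + 10_000 * ci + 1_000 * si + rep
                rng = np.random.default_rng(seed)
                events = []
                for p in range(9):
                    start = int(rng.integers(0, n_slices - span_slices + 1))
                    events.append(
                        synthetic.WrapEvent(
                            p, start, start + span_slices - 1, cov,
                            float(rng.uniform(0, 2 * np.pi)),
                        )
                    )
                spec = synthetic.SyntheticFieldSpec(
                    wrap_events=tuple(events),
                    n_nuclei=6,
                    blur_sigma_um=0.4 if noise else 0.0,
                    gaussian_sd=5.0 if noise else 0.0,
                    poisson=noise,
                    seed=seed,
                )
                stack, truth = synthetic.generate_field(spec)
                metrics = wrapping.compute_field_metrics(stack, params)
                matched = synthetic.match_pillars(metrics.per_pillar, truth)
                agree = matched["fully_wrapped"] == matched["true_fully_wrapped"]
                n_correct += int(agree.sum())
                n_total += len(matched)
                cells_wrapped[key] += int(matched["fully_wrapped"].sum())
                cells_total[key] += len(matched)
    return SweepResult(n_total, n_correct, cells_wrapped, cells_total)


@dataclass
class RecoveryResult:
    n_fields: int
    n_exact: int
    n_within_tol: int
    tol: float
    max_abs_error: float


def wi_recovery_study(
    n_fields: int = 100, noise: bool = True, seed0: int = 0, tol: float = 0.05
) -> RecoveryResult:
    """Computed WI vs ground-truth WI over randomized synthetic fields."""
    n_exact = n_within = 0
    max_err = 0.0
    params = wrapping.QuantParams()
    for i in range(n_fields):
        spec = synthetic.random_field_spec(seed0 + i, noise=noise)
        stack, truth = synthetic.generate_field(spec)
        metrics = wrapping.compute_field_metrics(stack, params)
        err = abs(metrics.wi - truth.expected_wi)
        n_exact += metrics.wi == truth.expected_wi
        n_within += err <= tol
        max_err = max(max_err, err)
    return RecoveryResult(n_fields, n_exact, n_within, tol, max_err)


@dataclass
class HertzRecovery:
    noiseless_rel_err: dict[str, float]  # material -> |E_hat - E| / E
    noisy_mean_E: dict[str, float]  # mean fitted modulus over noisy replicates (Pa)
    noisy_mean_rel_err: dict[str, float]  # |mean - true| / true
    ordering_preserved: bool  # E_X > E_Y > E_Z in every replicate
    n_replicates: int


def hertz_recovery_study(
    n_replicates: int = 30, noise_frac: float = 0.02, seed0: int = 0
) -> HertzRecovery:
    """Forward-simulate Hertz curves for the three materials and re-fit.

    Noiseless curves test numerical round-trip; noisy replicates add
    Gaussian force noise of ``noise_frac`` of the maximum force.  Ordering
    is checked per replicate across materials.
    """
    noiseless = {}
    for name, E in MATERIAL_MODULI.items():
        curve = synthetic.generate_force_curve(E=E, noise_sd=0.0)
        fit = mechanics.fit_hertz(curve)
        noiseless[name] = abs(fit.E - E) / E

    fits_by_material: dict[str, list[float]] = {m: [] for m in MATERIAL_MODULI}
    for mi, (name, E) in enumerate(MATERIAL_MODULI.items()):
        f_max = float(mechanics.hertz_force(200e-9, E, 0.5, 0.75e-6))
        for i in range(n_replicates):
            curve = synthetic.generate_force_curve(
                E=E, noise_sd=noise_frac * f_max, seed=seed0 + 1_000 * mi + i
            )
            fits_by_material[name].append(mechanics.fit_hertz(curve).E)

    noisy_mean = {m: float(np.mean(v)) for m, v in fits_by_material.items()}
    noisy_err = {
        m: abs(noisy_mean[m] - MATERIAL_MODULI[m]) / MATERIAL_MODULI[m]
        for m in fits_by_material
    }
    ordering = all(
        fits_by_material["X"][i] > fits_by_material["Y"][i] > fits_by_material["Z"][i]
        for i in range(n_replicates)
    )
    return HertzRecovery(noiseless, noisy_mean, noisy_err, ordering, n_replicates)


@dataclass
class HitCallRates:
    fpr: float
    tpr: float
    n_replicates: int


def hit_call_study(
    n_replicates: int = 200,
    control_mean: float = 1.0,
    field_sd: float = 0.1,
    delta: float = 0.3,
    n_fields: int = 27,
    seed0: int = 0,
) -> HitCallRates:
    """Operating characteristics of the 2-SD hit rule.

    Each replicate draws per-field WI values for a control and for a null
    compound (shift 0, contributes to the false-positive rate) and a true
    compound (shift ``delta``, contributes to the true-positive rate), then
    applies :func:`axonwrap.stats.call_hits`.
    """
    rng = np.random.default_rng(seed0)
    fp = tp = 0
    for _ in range(n_replicates):
        ctrl = rng.normal(control_mean, field_sd, n_fields)
        null = rng.normal(control_mean, field_sd, n_fields)
        true = rng.normal(control_mean + delta, field_sd, n_fields)
        summaries = [
            stats.ConditionSummary("DMSO", list(ctrl), float(ctrl.mean()),
                                   float(ctrl.std(ddof=1) / np.sqrt(n_fields)), n_fields),
            stats.ConditionSummary("null", list(null), float(null.mean()),
                                   float(null.std(ddof=1) / np.sqrt(n_fields)), n_fields),
            stats.ConditionSummary("shifted", list(true), float(true.mean()),
                                   float(true.std(ddof=1) / np.sqrt(n_fields)), n_fields),
        ]
        hits = stats.call_hits(summaries, "DMSO")
        fp += hits["null"]
        tp += hits["shifted"]
    return HitCallRates(fp / n_replicates, tp / n_replicates, n_replicates)
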