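"""Synthetic expression matrices and BAL cell-count tables with planted truth.

The generator emulates a single-instillation pulmonary exposure study:
three doses (18/54/162 ug) by three sacrifice times (1/3/28 days), replicated
treated animals per condition and vehicle controls per time point.  Gene
expression is produced directly on the normalized log2 scale (probe-level
microarray artifacts are out of scope); each gene follows a planted polynomial
surface in the shared normalized dose-time coordinates plus iid Gaussian
noise.  BAL differential counts follow a planted log2-scale trend on top of a
cell-type baseline, with multiplicative overdispersed integer noise.

Because the planted surfaces use the same coordinate convention as the model
fitter, every downstream stage (fold changes, surface fitting, responsive
region detection, dPOD labels, gene-cell correlation) has exact ground truth.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTROL, TREATED, ExposureDesign, dose_derivative, eval_surface, to_model_coords
from .errors import DuplicateIdentifierError, EmptyInputError, InvalidSpecError

GENE_CLASSES = ("flat", "time_only", "linear_dose", "quadratic_monotone_dose", "non_monotone_dose")

_NONINTERCEPT = ("d", "t", "d2", "t2", "dt")


@dataclass(frozen=True)
class GeneSurfaceSpec:
    """Planted log2 fold-change surface for one synthetic gene.

    ``coefficients`` maps polynomial terms (intercept, d, t, d2, t2, dt) on
    the normalized dose-time square to log2 units; ``klass`` records which
    qualitative behaviour the surface was planted to exhibit.
    """

    gene_id: str
    klass: str
    coefficients: Mapping[str, float]
    noise_sd: float = 0.2

    def __post_init__(self):
        if self.klass not in GENE_CLASSES:
            raise InvalidSpecError(f"unknown gene class {self.klass!r}")
        if self.noise_sd < 0:
            raise InvalidSpecError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        c = self.coefficients
        if self.klass == "flat" and any(c.get(k, 0.0) != 0.0 for k in _NONINTERCEPT):
            raise InvalidSpecError("flat gene must have zero non-intercept coefficients")
        if self.klass == "time_only" and any(c.get(k, 0.0) != 0.0 for k in ("d", "d2", "dt")):
            raise InvalidSpecError("time_only gene must have zero dose coefficients")
        if self.klass == "linear_dose" and c.get("d", 0.0) == 0.0:
            raise InvalidSpecError("linear_dose gene needs a nonzero d coefficient")
        if self.klass == "non_monotone_dose" and not self._dose_sign_changes():
            raise InvalidSpecError("non_monotone_dose gene must change dose-derivative sign in [0,1]")

    def _dose_sign_changes(self) -> bool:
        dd, tt = np.meshgrid(np.linspace(0, 1, 21), np.linspace(0, 1, 21), indexing="ij")
        g = dose_derivative(self.coefficients, dd, tt)
        return bool(np.any(g > 0) and np.any(g < 0))


@dataclass(frozen=True)
class CellTrendSpec:
    """Planted dose-time trend for one BAL cell type.

    The expected treated count is ``baseline_count * 2**trend(d, t)`` (the
    trend acts on the log2 scale); controls sit at the baseline.  ``dispersion``
    is the coefficient of variation of the multiplicative count noise.
    """

    cell_type: str
    baseline_count: float
    trend_coefficients: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.2

    def __post_init__(self):
        if self.baseline_count <= 0:
            raise InvalidSpecError(f"baseline_count must be positive, got {self.baseline_count}")
        if self.dispersion <= 0:
            raise InvalidSpecError(f"dispersion must be positive, got {self.dispersion}")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"duplicate {what}: {dups}")


def simulate_expression(
    design: ExposureDesign,
    specs: Sequence[GeneSurfaceSpec],
    baseline: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log2 expression matrix (genes x samples) plus annotation.

    Treated samples at (dose, time) have expected value
    ``baseline + surface(d, t)`` in normalized coordinates; controls sit at
    the baseline.  Noise is iid Gaussian per gene with the spec's noise_sd,
    drawn from ``design.seed`` so reruns are bit-identical.
    """
    if len(specs) == 0:
        raise EmptyInputError("need at least one gene spec")
    _check_unique([s.gene_id for s in specs], "gene_id")
    annotation = design.samples()
    treated = annotation["group"].to_numpy() == TREATED
    d = np.zeros(len(annotation))
    t = np.zeros(len(annotation))
    d[treated], t[treated] = to_model_coords(
        annotation.loc[treated, "dose"].to_numpy(),
        annotation.loc[treated, "time"].to_numpy(),
        design,
    )
    rng = np.random.default_rng([design.seed, 1])
    noise = rng.standard_normal((len(specs), len(annotation)))
    values = np.empty((len(specs), len(annotation)))
    for i, spec in enumerate(specs):
        mean = np.full(len(annotation), baseline)
        mean[treated] += eval_surface(spec.coefficients, d[treated], t[treated])
        values[i] = mean + spec.noise_sd * noise[i]
    expr = pd.DataFrame(values, index=[s.gene_id for s in specs], columns=annotation["sample_id"])
    expr.index.name = "gene_id"
    return expr, annotation


def simulate_bal_counts(
    design: ExposureDesign,
    specs: Sequence[CellTrendSpec],
) -> pd.DataFrame:
    """Simulate BAL differential counts per (cell type, animal).

    One animal cohort (treated per condition, controls per time point) is
    shared across cell types, mirroring a differential count of the same
    lavage fluid.  Counts are ``round(mu * Gamma(cv=dispersion))`` with mu the
    planted expectation: multiplicative overdispersed noise whose variance
    vanishes as dispersion -> 0, so zero-noise planted counts are recovered
    exactly in that limit.
    """
    if len(specs) == 0:
        raise EmptyInputError("need at least one cell trend spec")
    _check_unique([s.cell_type for s in specs], "cell_type")
    animals = design.samples().rename(columns={"sample_id": "animal_id"})
    animals["animal_id"] = "a_" + animals["animal_id"]
    treated = animals["group"].to_numpy() == TREATED
    d = np.zeros(len(animals))
    t = np.zeros(len(animals))
    d[treated], t[treated] = to_model_coords(
        animals.loc[treated, "dose"].to_numpy(),
        animals.loc[treated, "time"].to_numpy(),
        design,
    )
    rng = np.random.default_rng([design.seed, 2])
    frames = []
    for spec in specs:
        log2fc = np.zeros(len(animals))
        log2fc[treated] = eval_surface(spec.trend_coefficients, d[treated], t[treated])
        mu = spec.baseline_count * np.exp2(log2fc)
        shape = 1.0 / spec.dispersion**2
        counts = np.rint(mu * rng.gamma(shape, 1.0 / shape, size=len(animals))).astype(int)
        frame = animals.copy()
        frame.insert(0, "cell_type", spec.cell_type)
        frame["count"] = np.maximum(counts, 0)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[
        ["cell_type", "animal_id", "dose", "time", "group", "count"]
    ]


def default_gene_panel(
    n_linear: int = 25,
    n_quadratic: int = 25,
    n_flat: int = 100,
    n_time_only: int = 25,
    n_non_monotone: int = 25,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> list[GeneSurfaceSpec]:
    """Default 200-gene panel with planted classes.

    Monotone dose-responsive genes (linear and saturating-quadratic) have
    top-dose amplitudes |log2FC| in [1.0, 2.5], the magnitude range of clear
    transcriptional responders.  Time-only genes are modest (|c_t| in
    [0.2, 0.5]): sample-wise fold changes are taken against time-matched
    vehicle controls, which cancels shared kinetics, so purely time-dependent
    fold-change drift is expected to be small.  Non-monotone genes rise to a
    mid-dose peak of amplitude [0.8, 1.5] and return to baseline at the top
    dose.  Signs are random per gene.
    """
    rng = np.random.default_rng([seed, 3])
    specs: list[GeneSurfaceSpec] = []

    def sign() -> float:
        return float(rng.choice([-1.0, 1.0]))

    for i in range(n_linear):
        amp = sign() * rng.uniform(1.0, 2.5)
        specs.append(
            GeneSurfaceSpec(f"lin{i:03d}", "linear_dose", {"d": amp}, noise_sd)
        )
    for i in range(n_quadratic):
        top = rng.uniform(1.0, 2.5)
        a = rng.uniform(0.2, 0.8) * top  # split top amplitude between d and d2
        s = sign()
        specs.append(
            GeneSurfaceSpec(
                f"quad{i:03d}",
                "quadratic_monotone_dose",
                {"d": s * a, "d2": s * (top - a)},
                noise_sd,
            )
        )
    for i in range(n_flat):
        specs.append(GeneSurfaceSpec(f"flat{i:03d}", "flat", {}, noise_sd))
    for i in range(n_time_only):
        amp = sign() * rng.uniform(0.2, 0.5)
        specs.append(GeneSurfaceSpec(f"time{i:03d}", "time_only", {"t": amp}, noise_sd))
    for i in range(n_non_monotone):
        peak = sign() * rng.uniform(0.8, 1.5)
        # 4p*(d - d^2): peak p at d = 1/2, zero at both dose extremes
        specs.append(
            GeneSurfaceSpec(
                f"nonmono{i:03d}",
                "non_monotone_dose",
                {"d": 4 * peak, "d2": -4 * peak},
                noise_sd,
            )
        )
    return specs


def default_cell_panel() -> list[CellTrendSpec]:
    """Four BAL cell types with planted trends typical of particle instillation.

    Neutrophils surge dose-dependently from the earliest time point;
    eosinophils respond to dose with a late accent; macrophages are abundant
    and unresponsive; lymphocytes rise slowly (dose x time interaction).
    """
    return [
        CellTrendSpec("neutrophil", 50.0, {"d": 3.0}, 0.20),
        CellTrendSpec("eosinophil", 5.0, {"d": 1.5, "dt": 1.0}, 0.30),
        CellTrendSpec("macrophage", 200.0, {}, 0.15),
        CellTrendSpec("lymphocyte", 20.0, {"dt": 1.5}, 0.25),
    ]
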