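"""Bennett acceptance ratio (BAR) free-energy estimation over lambda windows.

For two neighbouring ensembles i and j with potential-energy differences
dU = U_j - U_i sampled in each ensemble, the free-energy difference dG
(kcal/mol) solves the self-consistency condition

    < 1 / (1 + exp(beta (dU - dG))) >_i  =  < 1 / (1 + exp(beta (-dU + dG))) >_j

with beta the reciprocal thermodynamic temperature in 1/(kcal/mol)
(beta = 1/(k_B T) ~ 1.688 at 298 K). The left side is increasing and the
right side decreasing in dG, so the residual has a unique root; it is found
by bracket expansion plus Brent's method.

An alchemical decoupling leg is a chain of such window pairs; the leg total
is the sum of window dGs. The binding free energy combines two legs,

    dG_bind = dG_water_leg - dG_complex_leg + restraint_correction,

i.e. with this sign convention a *negative* dG_bind means binding is
favorable when each leg measures the free energy of decoupling the ligand
from its environment. The restraint correction (if the complex leg was run
under restraints) is a user-supplied number, not estimated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .errors import NoOverlapError

#: Widest bracket (kcal/mol) tried before declaring the distributions
#: non-overlapping.
_MAX_BRACKET = 1.0e3


@dataclass
class WorkSamples:
    """Forward/backward dU = U_j - U_i samples for one window pair.

    ``forward`` was sampled in ensemble i, ``backward`` in ensemble j; both
    in kcal/mol. ``beta`` in 1/(kcal/mol).
    """

    forward: np.ndarray
    backward: np.ndarray
    beta: float = 1.0

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.forward.size == 0 or self.backward.size == 0:
            raise ValueError("both forward and backward sample sets must be non-empty")
        if not (np.isfinite(self.forward).all() and np.isfinite(self.backward).all()):
            raise ValueError("energy-difference samples must be finite")
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    def swapped(self) -> "WorkSamples":
        """The same window with the roles of the two ensembles exchanged."""
        return WorkSamples(-self.backward, -self.forward, self.beta)


@dataclass
class LambdaSchedule:
    """Electrostatic and van der Waals coupling-parameter lists.

    Defaults are a uniform 5-point electrostatic schedule and a nonuniform
    16-point vdW schedule (dense near full coupling), 21 lambda states in
    all, i.e. 19 window pairs. Each list starts at 0, ends at 1, strictly
    increasing.
    """

    electrostatic: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    vdw: tuple[float, ...] = (
        0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7,
        0.75, 0.8, 0.85, 0.9, 0.95, 1.0,
    )
    window_ns: float = 1.0

    def __post_init__(self):
        for name, lam in (("electrostatic", self.electrostatic), ("vdw", self.vdw)):
            lam = tuple(lam)
            if lam[0] != 0.0 or lam[-1] != 1.0 or any(
                b <= a for a, b in zip(lam, lam[1:])
            ):
                raise ValueError(
                    f"{name} lambda list must start at 0, end at 1, strictly increasing"
                )

    @property
    def n_states(self) -> int:
        return len(self.electrostatic) + len(self.vdw)

    @property
    def n_window_pairs(self) -> int:
        return (len(self.electrostatic) - 1) + (len(self.vdw) - 1)


def _residual(dg: float, samples: WorkSamples) -> float:
    beta = samples.beta
    lhs = float(np.mean(expit(-beta * (samples.forward - dg))))
    rhs = float(np.mean(expit(beta * (samples.backward - dg))))
    return lhs - rhs


def bar_solve(samples: WorkSamples, tolerance: float = 1e-8) -> float:
    """Solve the BAR self-consistency equation for dG (kcal/mol).

    Deterministic for fixed inputs; raises :class:`NoOverlapError` when no
    finite bracket within +-1e3 kcal/mol contains the root (forward and
    backward distributions too far apart — add more lambda windows).
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    # Crude starting guess: midpoint of the two sample means of dU.
    guess = 0.5 * (float(samples.forward.mean()) + float(samples.backward.mean()))
    half = 1.0
    lo, hi = guess - half, guess + half
    while _residual(lo, samples) > 0 or _residual(hi, samples) < 0:
        half *= 2.0
        lo, hi = guess - half, guess + half
        if half > _MAX_BRACKET:
            raise NoOverlapError(
                "BAR self-consistency root not bracketable within "
                f"+-{_MAX_BRACKET:g} kcal/mol of the sample means; the window's "
                "forward/backward distributions do not overlap — use more, "
                "closer lambda windows"
            )
    root = float(brentq(_residual, lo, hi, args=(samples,), xtol=tolerance))
    # A root formally always exists, but when the two distributions are
    # disjoint the Fermi acceptance terms saturate (mean ~ 0 or ~ 1) and the
    # residual is an underflow plateau: the located "root" carries no
    # information.
    acceptance = float(np.mean(expit(-samples.beta * (samples.forward - root))))
    if acceptance < 1e-12 or acceptance > 1.0 - 1e-12:
        raise NoOverlapError(
            f"acceptance ratio saturated ({acceptance:g}) at the solution; the "
            "forward/backward distributions do not overlap — use more, closer "
            "lambda windows"
        )
    return root


def bar_uncertainty(
    samples: WorkSamples,
    n_bootstrap: int = 200,
    seed: int = 0,
    block: int = 1,
    tolerance: float = 1e-8,
) -> float:
    """Standard error of the BAR estimate by seeded (block) bootstrap.

    ``block`` > 1 resamples contiguous blocks, for serially correlated input.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_bootstrap):
        fwd = _block_resample(samples.forward, rng, block)
        bwd = _block_resample(samples.backward, rng, block)
        try:
            estimates.append(bar_solve(WorkSamples(fwd, bwd, samples.beta), tolerance))
        except NoOverlapError:
            continue
    return float(np.std(estimates, ddof=1)) if len(estimates) > 1 else float("nan")


def _block_resample(x: np.ndarray, rng: np.random.Generator, block: int) -> np.ndarray:
    n = x.size
    if block <= 1:
        return x[rng.integers(0, n, n)]
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, max(n - block, 1), n_blocks)
    return np.concatenate([x[s : s + block] for s in starts])[:n]


@dataclass
class BindingFreeEnergyLedger:
    """Per-window and per-leg bookkeeping for a two-leg binding estimate."""

    complex_windows: list[float] = field(default_factory=list)
    water_windows: list[float] = field(default_factory=list)
    restraint_correction: float = 0.0
    sign_convention: str = (
        "dG_bind = water_leg - complex_leg + restraint_correction; "
        "negative = favorable binding"
    )

    @property
    def complex_leg(self) -> float:
        return float(sum(self.complex_windows))

    @property
    def water_leg(self) -> float:
        return float(sum(self.water_windows))

    @property
    def binding_dg(self) -> float:
        return self.water_leg - self.complex_leg + self.restraint_correction

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sign_convention": self.sign_convention,
            "complex_windows_kcal_mol": self.complex_windows,
            "water_windows_kcal_mol": self.water_windows,
            "complex_leg_kcal_mol": self.complex_leg,
            "water_leg_kcal_mol": self.water_leg,
            "restraint_correction_kcal_mol": self.restraint_correction,
            "binding_dG_kcal_mol": self.binding_dg,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def chain_windows(
    windows: Sequence[WorkSamples],
    schedule: LambdaSchedule | None = None,
    tolerance: float = 1e-8,
) -> tuple[float, list[float]]:
    """Sum per-window BAR estimates into a decoupling-leg total.

    If a ``schedule`` is given, the window count must equal its number of
    window pairs. A failing window aborts with its index in the message.
    """
    if schedule is not None and len(windows) != schedule.n_window_pairs:
        raise ValueError(
            f"expected {schedule.n_window_pairs} windows for this schedule, "
            f"got {len(windows)}"
        )
    per_window = []
    for idx, samples in enumerate(windows):
        try:
            per_window.append(bar_solve(samples, tolerance))
        except NoOverlapError as exc:
            raise NoOverlapError(f"window {idx} failed: {exc}") from exc
    return float(sum(per_window)), per_window


def read_window_file(path: str | Path, beta: float = 1.0) -> WorkSamples:
    """Read one window's two-column text file: ensemble label ('i'/'j'), dU."""
    fwd, bwd = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, value = line.split()
        (fwd if label == "i" else bwd).append(float(value))
    return WorkSamples(np.array(fwd), np.array(bwd), beta)
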