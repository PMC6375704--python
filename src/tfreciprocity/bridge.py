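"""Converting between the TF viewpoint and the DNA viewpoint.

Single-molecule tracking observes the TF, which shuttles between a
specifically-bound microstate b and a not-specifically-bound microstate nb.
The measured quantities are the average search time (reciprocal of the
binding label k+[DX]) and the average bound time (reciprocal of the unbinding
label k-), giving kappa = bound_time / search_time per experimental scenario.

What the analysis needs is the DNA viewpoint: the fraction P of X-specific
sites bound by X.  The two viewpoints meet through the bound complex:
with alpha_X = [DX]_tot / [X]_tot,

    alpha_X * P = kappa / (1 + kappa),

so kappa = B alpha / (A + B (1 - alpha)) where, up to a scalar, A is the total
steady-state probability of DNA microstates with the measured TF unbound and
B with it bound.  alpha_X is generally unknown, but it cancels in the ratios
P4/P1 and P3/P2 used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ScenarioTimes",
    "ResidenceTimeTable",
    "KappaSet",
    "AlphaRatios",
    "kappa_from_times",
    "tf_bound_fraction",
    "kappa_from_dna",
    "kappa_from_fraction",
    "fraction_from_kappa",
    "round_to_sig_figs",
]

#: Scenario meanings: 1 Sox2 measured / Oct4 absent; 4 Sox2 measured / Oct4
#: induced; 2 Oct4 measured / Sox2 absent; 3 Oct4 measured / Sox2 induced.
SCENARIOS = (1, 2, 3, 4)

_CSV_COLUMNS = [
    "scenario",
    "search_mean_s",
    "search_sd_s",
    "bound_mean_s",
    "bound_sd_s",
    "n_samples",
]


@dataclass(frozen=True)
class ScenarioTimes:
    """Residence-time summary for one scenario (seconds)."""

    search_mean: float
    search_sd: float
    bound_mean: float
    bound_sd: float
    n_samples: int = 3

    def __post_init__(self) -> None:
        if not (self.search_mean > 0 and self.bound_mean > 0):
            raise ValueError("mean residence times must be strictly positive")
        if self.search_sd < 0 or self.bound_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")

    @property
    def kappa(self) -> float:
        return kappa_from_times(self.search_mean, self.bound_mean)

    def sem(self, n_samples: int | None = None) -> tuple[float, float]:
        """(search SEM, bound SEM) with SEM = SD / sqrt(N); default N as recorded."""
        n = self.n_samples if n_samples is None else n_samples
        return self.search_sd / math.sqrt(n), self.bound_sd / math.sqrt(n)


@dataclass(frozen=True)
class ResidenceTimeTable:
    """The four-scenario residence-time dataset with uncertainties."""

    scenarios: dict

    def __post_init__(self) -> None:
        if set(self.scenarios) != set(SCENARIOS):
            raise ValueError(f"scenario indices must be exactly {set(SCENARIOS)}")

    def __getitem__(self, i: int) -> ScenarioTimes:
        return self.scenarios[i]

    def kappas(self, precision: str = "full") -> "KappaSet":
        """kappa_i per scenario, by ratio of mean times.

        ``precision='full'`` uses the full-precision ratios;
        ``precision='printed'`` rounds each kappa to two significant figures,
        matching the convention of published summary tables.
        """
        ks = {i: self.scenarios[i].kappa for i in SCENARIOS}
        if precision == "printed":
            ks = {i: round_to_sig_figs(k, 2) for i, k in ks.items()}
        elif precision != "full":
            raise ValueError("precision must be 'full' or 'printed'")
        return KappaSet(ks[1], ks[2], ks[3], ks[4])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": i,
                "search_mean_s": s.search_mean,
                "search_sd_s": s.search_sd,
                "bound_mean_s": s.bound_mean,
                "bound_sd_s": s.bound_sd,
                "n_samples": s.n_samples,
            }
            for i, s in sorted(self.scenarios.items())
        ]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResidenceTimeTable":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"residence-time table is missing columns {missing}")
        scenarios = {}
        for _, row in df.iterrows():
            i = int(row["scenario"])
            scenarios[i] = ScenarioTimes(
                search_mean=float(row["search_mean_s"]),
                search_sd=float(row["search_sd_s"]),
                bound_mean=float(row["bound_mean_s"]),
                bound_sd=float(row["bound_sd_s"]),
                n_samples=int(row["n_samples"]),
            )
        return cls(scenarios)

    @classmethod
    def from_csv(cls, path) -> "ResidenceTimeTable":
        return cls.from_dataframe(pd.read_csv(Path(path)))


@dataclass(frozen=True)
class KappaSet:
    """The four dimensionless kappa_i = binding label / unbinding label."""

    kappa1: float
    kappa2: float
    kappa3: float
    kappa4: float

    def __post_init__(self) -> None:
        for name in ("kappa1", "kappa2", "kappa3", "kappa4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.kappa1, self.kappa2, self.kappa3, self.kappa4)


@dataclass(frozen=True)
class AlphaRatios:
    """alpha_X = [DX]_tot / [X]_tot per TF (site over TF total concentration)."""

    alpha_S: float
    alpha_O: float

    def __post_init__(self) -> None:
        if not (self.alpha_S > 0 and self.alpha_O > 0):
            raise ValueError("alpha ratios must be strictly positive")


def kappa_from_times(search_mean: float, bound_mean: float) -> float:
    """kappa from mean residence times: bound_mean / search_mean.

    The binding and unbinding labels are the reciprocals of the mean search
    and bound times, so their ratio is the ratio of means (not the mean of
    per-molecule ratios).
    """
    if not (search_mean > 0 and bound_mean > 0):
        raise ValueError("residence times must be strictly positive")
    return bound_mean / search_mean


def tf_bound_fraction(kappa: float) -> float:
    """Fraction of TF molecules specifically bound: Pr(b) = kappa/(1+kappa)."""
    if not kappa > 0:
        raise ValueError(f"kappa must be strictly positive, got {kappa}")
    return kappa / (1.0 + kappa)


def kappa_from_dna(A: float, B: float, alpha: float) -> float:
    """TF-viewpoint kappa from DNA-viewpoint terms: B alpha / (A + B (1-alpha)).

    A and B are proportional to the total steady-state probability of DNA
    microstates with the measured TF unbound (A) and bound (B).
    """
    if A < 0 or B < 0:
        raise ValueError("A and B must be nonnegative")
    if not alpha > 0:
        raise ValueError("alpha must be strictly positive")
    den = A + B * (1.0 - alpha)
    if den <= 0:
        raise ZeroDivisionError(f"A + B(1-alpha) = {den} is not positive")
    return B * alpha / den


def kappa_from_fraction(P: float, alpha: float) -> float:
    """Invert alpha * P = kappa/(1+kappa): kappa = alpha P / (1 - alpha P)."""
    if not (0 < P <= 1):
        raise ValueError("bound fraction must lie in (0, 1]")
    if not alpha > 0:
        raise ValueError("alpha must be strictly positive")
    x = alpha * P
    if x >= 1:
        raise ValueError(f"alpha * P = {x} >= 1 is inconsistent with a finite kappa")
    return x / (1.0 - x)


def fraction_from_kappa(kappa: float, alpha: float) -> float:
    """Bound fraction of sites P = kappa / (alpha (1 + kappa)).

    Raises when the result exceeds 1, which signals an alpha inconsistent with
    the supplied kappa.
    """
    if not kappa > 0:
        raise ValueError("kappa must be strictly positive")
    if not alpha > 0:
        raise ValueError("alpha must be strictly positive")
    P = kappa / (alpha * (1.0 + kappa))
    if P > 1.0:
        raise ValueError(
            f"P = {P:.4g} > 1: alpha = {alpha} is inconsistent with kappa = {kappa}"
        )
    return P


def round_to_sig_figs(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (half-even, via the float repr)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)
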