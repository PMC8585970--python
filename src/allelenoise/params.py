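"""Generative-model parameters for the stochastic allele-silencing simulator.

The simulator draws, for every cell, a shared (extrinsic) log-normal factor,
two independent binomial active-copy counts (one per allele, ``ploidy_N``
copies each, per-copy silencing probability ``silencing_q``), independent
per-allele (intrinsic) log-normal factors, per-experiment channel gains and
additive detector noise.  The defaults describe a diploid tissue measured
over three independent imaging sessions, with an "introns"-like low silencing
rate reserved for the group presets below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from ._exceptions import ParameterError

GainSpec = Union[float, Sequence[float]]

#: Per-copy silencing probabilities used for the two canonical reporter
#: groups: intron-bearing alleles are rarely silenced, intronless alleles
#: frequently.  These drive the two-group pipeline preset.
INTRONS_Q = 0.02
INTRONLESS_Q = 0.30


@dataclass
class SimulationParams:
    """Parameters of the per-copy stochastic silencing model.

    Attributes
    ----------
    n_experiments, cells_per_experiment
        Dataset layout: independent imaging sessions and cells per session.
    ploidy_N
        Gene copies per allele per nucleus (2 models a diploid muscle
        nucleus; 32 a polyploid intestine nucleus).
    silencing_q
        Probability that a single copy is epigenetically silenced, in [0, 1].
    base_expression
        Mean signal of a fully active allele, arbitrary detector units.
    sigma_extrinsic, sigma_intrinsic
        Log-scale standard deviations of the shared cell-state factor and of
        the per-allele fluctuation; both log-normal with unit median.
    gain_red, gain_green
        Channel gain multipliers; a scalar applies to every experiment, a
        sequence gives one gain per experiment.
    measurement_sd
        Additive Gaussian detector noise (same units as ``base_expression``).
    seed
        Master seed; identical (params, seed) reproduce identical datasets.
    """

    n_experiments: int = 3
    cells_per_experiment: int = 60
    ploidy_N: int = 2
    silencing_q: float = 0.2
    base_expression: float = 1000.0
    sigma_extrinsic: float = 0.3
    sigma_intrinsic: float = 0.1
    gain_red: GainSpec = 1.0
    gain_green: GainSpec = 1.0
    measurement_sd: float = 5.0
    seed: int = 0
    group_label: str = "group"
    tissue: str = "muscle"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_experiments, (int, np.integer)) and self.n_experiments >= 1):
            raise ParameterError("n_experiments must be an integer >= 1")
        if not (isinstance(self.cells_per_experiment, (int, np.integer)) and self.cells_per_experiment >= 1):
            raise ParameterError("cells_per_experiment must be an integer >= 1")
        if not (isinstance(self.ploidy_N, (int, np.integer)) and self.ploidy_N >= 1):
            raise ParameterError("ploidy_N must be an integer >= 1")
        if not (0.0 <= self.silencing_q <= 1.0):
            raise ParameterError("silencing_q must lie in [0, 1]")
        if not self.base_expression > 0:
            raise ParameterError("base_expression must be > 0")
        if self.sigma_extrinsic < 0:
            raise ParameterError("sigma_extrinsic must be >= 0")
        if self.sigma_intrinsic < 0:
            raise ParameterError("sigma_intrinsic must be >= 0")
        if self.measurement_sd < 0:
            raise ParameterError("measurement_sd must be >= 0")
        for name in ("gain_red", "gain_green"):
            g = self.gains(name)
            if np.any(g <= 0):
                raise ParameterError(f"{name} must be > 0 (per experiment)")

    def gains(self, name: str) -> np.ndarray:
        """Per-experiment gain vector for ``gain_red`` or ``gain_green``."""
        raw = getattr(self, name)
        g = np.atleast_1d(np.asarray(raw, dtype=float))
        if g.size == 1:
            return np.full(self.n_experiments, float(g[0]))
        if g.size != self.n_experiments:
            raise ParameterError(
                f"{name} must be a scalar or length-{self.n_experiments} sequence"
            )
        return g


def two_group_params(
    seed: int,
    *,
    ploidy_N: int = 2,
    n_experiments: int = 3,
    cells_per_experiment: int = 60,
    tissue: str = "muscle",
    q_introns: float = INTRONS_Q,
    q_intronless: float = INTRONLESS_Q,
    **extra,
) -> tuple[SimulationParams, SimulationParams]:
    """Parameter pair for the canonical introns-vs-intronless contrast."""
    ss = np.random.SeedSequence(seed).spawn(2)
    mk = lambda q, lab, s: SimulationParams(
        n_experiments=n_experiments,
        cells_per_experiment=cells_per_experiment,
        ploidy_N=ploidy_N,
        silencing_q=q,
        seed=int(s.generate_state(1)[0] % 2**31),
        group_label=lab,
        tissue=tissue,
        **extra,
    )
    return mk(q_introns, "introns", ss[0]), mk(q_intronless, "intronless", ss[1])
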