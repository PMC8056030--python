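"""Synthetic study generator: Markov coding sequences + coupled rates.

Sequences are drawn from a first-order Markov chain over {A,C,G,U} started
at its stationary distribution.  This family is chosen deliberately: the
adjacent-base redundancy D2 measures exactly first-order dependence, so
the generator spans the statistic's full range and admits closed forms —

* theoretical D1 = 2 + Σ_i π_i log2 π_i,
* theoretical D2 = −2 Σ_i π_i log2 π_i + Σ_ij π_i T_ij log2(π_i T_ij),

where π is the stationary distribution and T the transition matrix.  With
consistent marginals theoretical D2 equals the mutual information of the
stationary adjacent pair and is therefore non-negative.

Folding rates are coupled linearly to one chosen sequence parameter:
ln kf = β0 + β1·x + ε with ε ~ N(0, σ).  The implied population
correlation, given the realized parameter spread σx, is
ρ = β1 σx / sqrt(β1² σx² + σ²); it is recorded in the truth file so
recovery tests have an exact target.

Defaults mirror the study design this test bed emulates: 100 proteins of
100 codons, 56 two-state / 44 multistate folders, 21 all-α / 39 all-β /
40 α-β, and a moderate positive coupling of ln kf to D12 (the single-base
redundancy of the second codon position).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, ModelError
from .infostats import parameter_set
from .sequence_io import (
    BASES,
    KineticClass,
    MrnaRecord,
    PARAMETER_COLUMNS,
    StructuralClass,
    StudyDataset,
    write_dataset,
)

_STATIONARY_ATOL = 1e-10
_ROWSUM_ATOL = 1e-12


@dataclass(frozen=True)
class MarkovModel:
    """First-order Markov chain over {A,C,G,U}.

    ``pi`` is the stationary base distribution; row i of ``T`` is the
    distribution of the next base given current base i.  ``pi`` must be a
    stationary vector of ``T`` so the chain can be started in equilibrium
    and the theoretical D1/D2 apply without burn-in.
    """

    pi: tuple[float, float, float, float]
    T: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if pi.shape != (4,) or T.shape != (4, 4):
            raise ModelError("pi must be length 4 and T must be 4x4")
        if (pi < 0).any() or (T < 0).any():
            raise ModelError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > _ROWSUM_ATOL:
            raise ModelError("pi must sum to 1")
        if np.abs(T.sum(axis=1) - 1.0).max() > _ROWSUM_ATOL:
            raise ModelError("each row of T must sum to 1")
        if np.abs(pi @ T - pi).max() > _STATIONARY_ATOL:
            raise ModelError("pi is not stationary for T (pi @ T != pi)")
        object.__setattr__(self, "pi", tuple(float(v) for v in pi))
        object.__setattr__(
            self, "T", tuple(tuple(float(v) for v in row) for row in T)
        )

    @classmethod
    def from_transition(cls, T: Sequence[Sequence[float]]) -> "MarkovModel":
        """Build a model from T alone, solving for its stationary vector."""
        T = np.asarray(T, dtype=float)
        vals, vecs = np.linalg.eig(T.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi) / np.abs(pi).sum()
        # polish with a few power iterations for tight stationarity
        for _ in range(200):
            nxt = pi @ T
            if np.abs(nxt - pi).max() < 1e-15:
                break
            pi = nxt
        return cls(pi=tuple(pi), T=tuple(map(tuple, T)))

    @classmethod
    def uniform(cls) -> "MarkovModel":
        """Independent, equiprobable bases (D1 = D2 = 0)."""
        return cls(pi=(0.25,) * 4, T=((0.25,) * 4,) * 4)

    @classmethod
    def random(cls, rng: np.random.Generator, concentration: float = 5.0) -> "MarkovModel":
        """Random chain with Dirichlet rows (ergodic w.p. 1)."""
        T = rng.dirichlet(np.full(4, concentration), size=4)
        return cls.from_transition(T)


def default_model() -> MarkovModel:
    """Default generator chain: uniform composition, mild self-preference.

    T = 0.8·uniform + 0.2·identity keeps the stationary distribution
    uniform (theoretical D1 = 0) while giving a detectable adjacent-base
    dependence (theoretical D2 ≈ 0.078 bits).
    """
    T = np.full((4, 4), 0.2) + 0.2 * np.eye(4)
    return MarkovModel(pi=(0.25,) * 4, T=tuple(map(tuple, T)))


def theoretical_d1(model: MarkovModel) -> float:
    """D1 evaluated at the model's stationary distribution, in bits."""
    pi = np.asarray(model.pi)
    nz = pi[pi > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def theoretical_d2(model: MarkovModel) -> float:
    """D2 evaluated at the stationary pair distribution p_ij = π_i T_ij."""
    pi = np.asarray(model.pi)
    T = np.asarray(model.T)
    pij = pi[:, None] * T
    nz1 = pi[pi > 0]
    nz2 = pij[pij > 0]
    return float(
        -2.0 * np.sum(nz1 * np.log2(nz1)) + np.sum(nz2 * np.log2(nz2))
    )


def generate_sequence(
    model: MarkovModel, length: int, seed: int | np.random.Generator
) -> str:
    """Draw one sequence: first base from π, the rest from T; seeded replay."""
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum_pi = np.cumsum(model.pi)
    cum_T = np.cumsum(np.asarray(model.T), axis=1)
    # guard against rounding so searchsorted never overflows index 3
    cum_pi[-1] = cum_T[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.intp)
    state = int(np.searchsorted(cum_pi, u[0], side="right"))
    out[0] = state
    rows = [list(row) for row in cum_T]
    for k in range(1, length):
        uk = u[k]
        row = rows[state]
        if uk < row[0]:
            state = 0
        elif uk < row[1]:
            state = 1
        elif uk < row[2]:
            state = 2
        else:
            state = 3
        out[k] = state
    letters = np.array(list(BASES))
    return "".join(letters[out])


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Settings for one synthetic study (the TS1/TS2 stand-in).

    ``ln_kf = beta0 + beta1·x + N(0, noise_sd)`` where x is
    ``target_parameter`` computed on each generated sequence.
    """

    n_proteins: int = 100
    length: int = 300
    target_parameter: str = "D12"
    beta0: float = 5.0
    beta1: float = 40.0
    noise_sd: float = 1.5
    seed: int = 0
    structural_fractions: tuple[float, float, float] = (0.21, 0.39, 0.40)
    kinetic_fractions: tuple[float, float] = (0.56, 0.44)
    model_per_group: Mapping[str, MarkovModel] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 3:
            raise ConfigError("n_proteins must be >= 3")
        if self.length < 6 or self.length % 3 != 0:
            raise ConfigError("length must be a codon multiple >= 6")
        if self.target_parameter not in PARAMETER_COLUMNS:
            raise ConfigError(
                f"target_parameter must be one of {PARAMETER_COLUMNS}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name, fr in (
            ("structural_fractions", self.structural_fractions),
            ("kinetic_fractions", self.kinetic_fractions),
        ):
            if min(fr) < 0 or abs(sum(fr) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")


@dataclass(frozen=True)
class StudyTruth:
    """Ground truth for a generated study, for recovery harnesses."""

    target_parameter: str
    beta0: float
    beta1: float
    noise_sd: float
    seed: int
    parameter_values: tuple[float, ...]
    sigma_x: float
    rho: float

    def to_json(self) -> str:
        d = {
            "target_parameter": self.target_parameter,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "sigma_x": self.sigma_x,
            "rho": self.rho,
            "parameter_values": list(self.parameter_values),
        }
        return json.dumps(d, indent=2)


def _counts_from_fractions(fractions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment so group sizes hit fractions exactly."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(v)) for v in raw]
    rem = n - sum(counts)
    order = np.argsort([c - v for c, v in zip(counts, raw)])
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_study(config: SyntheticStudyConfig) -> tuple[StudyDataset, StudyTruth]:
    """Generate one full synthetic study and its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    models = dict(config.model_per_group or {"all": default_model()})

    struct_labels = [
        sc
        for sc, c in zip(
            StructuralClass, _counts_from_fractions(config.structural_fractions, config.n_proteins)
        )
        for _ in range(c)
    ]
    kin_labels = [
        kc
        for kc, c in zip(
            KineticClass, _counts_from_fractions(config.kinetic_fractions, config.n_proteins)
        )
        for _ in range(c)
    ]
    rng.shuffle(struct_labels)
    rng.shuffle(kin_labels)

    sequences = []
    xs = []
    for i in range(config.n_proteins):
        model = models.get(struct_labels[i].value, models.get("all"))
        if model is None:
            raise ConfigError(
                f"model_per_group has no entry for {struct_labels[i].value!r} or 'all'"
            )
        seq = generate_sequence(model, config.length, rng)
        sequences.append(seq)
        xs.append(parameter_set(seq).to_dict()[config.target_parameter])
    xs = np.array(xs)
    noise = (
        rng.normal(0.0, config.noise_sd, size=config.n_proteins)
        if config.noise_sd > 0
        else np.zeros(config.n_proteins)
    )
    ln_kf = config.beta0 + config.beta1 * xs + noise

    width = len(str(config.n_proteins))
    records = tuple(
        MrnaRecord(
            id=f"SYN{i + 1:0{width}d}",
            sequence=sequences[i],
            structural_class=struct_labels[i],
            kinetic_class=kin_labels[i],
            ln_kf=float(ln_kf[i]),
        )
        for i in range(config.n_proteins)
    )
    sigma_x = float(np.std(xs, ddof=1))
    denom = np.hypot(config.beta1 * sigma_x, config.noise_sd)
    rho = float(config.beta1 * sigma_x / denom) if denom > 0 else 0.0
    truth = StudyTruth(
        target_parameter=config.target_parameter,
        beta0=config.beta0,
        beta1=config.beta1,
        noise_sd=config.noise_sd,
        seed=config.seed,
        parameter_values=tuple(float(v) for v in xs),
        sigma_x=sigma_x,
        rho=rho,
    )
    dataset = StudyDataset(records=records, provenance=f"synthetic seed={config.seed}")
    return dataset, truth


def write_study(
    dataset: StudyDataset,
    truth: StudyTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit FASTA + annotation table + truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "annotations": outdir / "annotations.csv",
        "truth": outdir / "truth.json",
    }
    write_dataset(dataset, paths["fasta"], paths["annotations"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
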