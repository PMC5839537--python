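"""Synthetic Cq-table generator with planted ground truth.

The generative model matches the structure the stability algorithms assume:

    Cq[g, (i, s)] = mu_g + delta[g, group_i] + L[(i, s)] + eps

with a per-sample loading effect L ~ N(0, loading_sd^2) shared by all genes
(what normalization is meant to remove), gene-specific technical noise
eps ~ N(0, noise_sd_g^2), and optional group-specific regulation shifts
delta for designated unstable genes. Optional technical duplicates add
independent N(0, replicate_sd^2) per well. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from refstab.data_io import CqTable
from refstab.errors import ConfigError

#: Tissue panel used by the paper-like preset.
PRESET_TISSUES = [
    "mammary_gland", "kidney", "spleen", "liver", "heart", "intestine",
    "ovary", "lung", "muscle", "brain", "subcutaneous_fat", "testis",
]


@dataclass
class SimConfig:
    """Parameters of the Cq generative model.

    `seed` is mandatory: a fixed seed reproduces the table bit-for-bit.
    Group sizes may be unbalanced but each group needs >= 2 samples.
    """

    genes: list[str]
    group_sizes: dict[str, int]
    baseline_cq: dict[str, float]
    noise_sd: dict[str, float]
    loading_sd: float
    seed: int
    regulation: dict[tuple[str, str], float] = field(default_factory=dict)
    replicate_sd: float | None = None
    n_subjects: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not self.genes:
            raise ConfigError("need at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("gene names must be unique")
        for g in self.genes:
            if g not in self.baseline_cq:
                raise ConfigError(f"no baseline Cq for gene {g!r}")
            if g not in self.noise_sd:
                raise ConfigError(f"no noise SD for gene {g!r}")
            if self.noise_sd[g] < 0:
                raise ConfigError(f"noise SD for {g!r} must be >= 0")
            if self.baseline_cq[g] <= 0:
                raise ConfigError(f"baseline Cq for {g!r} must be > 0")
        if self.loading_sd < 0:
            raise ConfigError("loading_sd must be >= 0")
        if self.replicate_sd is not None and self.replicate_sd < 0:
            raise ConfigError("replicate_sd must be >= 0")
        for grp, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {grp!r} has size {n}; need >= 2")
        for (g, grp) in self.regulation:
            if g not in self.genes:
                raise ConfigError(f"regulation references unknown gene {g!r}")
            if grp not in self.group_sizes:
                raise ConfigError(f"regulation references unknown group {grp!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def planted_instability(self) -> dict[str, float]:
        """Planted per-gene instability: sqrt(noise^2 + between-group
        variance contributed by regulation shifts), in cycles.

        This is the ground-truth ordering key used by recovery tests.
        """
        n_total = self.n_samples
        out: dict[str, float] = {}
        for g in self.genes:
            shifts = np.zeros(n_total)
            pos = 0
            for grp, n in self.group_sizes.items():
                shifts[pos:pos + n] = self.regulation.get((g, grp), 0.0)
                pos += n
            out[g] = float(np.sqrt(self.noise_sd[g] ** 2 + shifts.var()))
        return out


@dataclass
class SimTruth:
    """Realized parameters of one simulated table."""

    config: SimConfig
    loading: dict[str, float]
    instability: dict[str, float]
    stable_order: list[str]

    def to_json(self) -> str:
        payload = {
            "seed": self.config.seed,
            "genes": self.config.genes,
            "group_sizes": self.config.group_sizes,
            "baseline_cq": self.config.baseline_cq,
            "noise_sd": self.config.noise_sd,
            "loading_sd": self.config.loading_sd,
            "replicate_sd": self.config.replicate_sd,
            "regulation": {f"{g}|{grp}": v
                           for (g, grp), v in self.config.regulation.items()},
            "loading": self.loading,
            "instability": self.instability,
            "stable_order": self.stable_order,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def simulate_cq(config: SimConfig) -> tuple[CqTable, SimTruth]:
    """Draw one Cq table (and its truth sidecar) from the model."""
    ss = np.random.SeedSequence(config.seed)
    rng_load, rng_noise, rng_rep = (np.random.default_rng(s) for s in ss.spawn(3))

    genes = list(config.genes)
    samples: list[str] = []
    group_of: dict[str, str] = {}
    subject_of: dict[str, str] = {}
    delta_cols: list[np.ndarray] = []
    for grp, n in config.group_sizes.items():
        for i in range(n):
            s = f"{grp}_{i + 1}"
            samples.append(s)
            group_of[s] = grp
            subject_of[s] = f"animal_{(i % config.n_subjects) + 1}"
            delta_cols.append(np.array(
                [config.regulation.get((g, grp), 0.0) for g in genes]))

    n_samples = len(samples)
    loading = rng_load.normal(0.0, config.loading_sd, size=n_samples)
    mu = np.array([config.baseline_cq[g] for g in genes])[:, None]
    sd = np.array([config.noise_sd[g] for g in genes])[:, None]
    eps = rng_noise.normal(size=(len(genes), n_samples)) * sd
    cq = mu + np.stack(delta_cols, axis=1) + loading[None, :] + eps

    if config.replicate_sd is not None:
        cols: list[str] = []
        cq_rep = np.empty((len(genes), 2 * n_samples))
        sample_of: dict[str, str] = {}
        replicate_of: dict[str, str] = {}
        g2: dict[str, str] = {}
        s2: dict[str, str] = {}
        well = rng_rep.normal(0.0, config.replicate_sd,
                              size=(len(genes), n_samples, 2))
        for j, s in enumerate(samples):
            for r in range(2):
                col = f"{s}::r{r + 1}"
                cols.append(col)
                sample_of[col] = s
                replicate_of[col] = f"r{r + 1}"
                g2[col] = group_of[s]
                s2[col] = subject_of[s]
                cq_rep[:, 2 * j + r] = cq[:, j] + well[:, j, r]
        table = CqTable(genes=genes, samples=cols, cq=cq_rep, group_of=g2,
                        subject_of=s2, sample_of=sample_of,
                        replicate_of=replicate_of)
    else:
        table = CqTable(genes=genes, samples=samples, cq=cq,
                        group_of=group_of, subject_of=subject_of)

    instability = config.planted_instability()
    truth = SimTruth(
        config=config,
        loading={s: float(v) for s, v in zip(samples, loading)},
        instability=instability,
        stable_order=sorted(genes, key=lambda g: instability[g]),
    )
    return table, truth


def preset_paper_like(seed: int = 0,
                      loading_sd: float = 0.7,
                      replicate_sd: float | None = None) -> SimConfig:
    """A 10-gene x 12-tissue configuration emulating the published study.

    54 samples over 12 unbalanced tissue groups; baselines span ~19-26
    cycles; noise SDs are graded so four genes (RPS9, UXT, RPL4, RPS23) are
    clearly most stable and two (RPS15 by noise, B2M by tissue-specific
    regulation in spleen/liver/intestine) clearly worst.
    """
    group_sizes = {t: 5 for t in PRESET_TISSUES}
    group_sizes["mammary_gland"] = 4
    group_sizes["brain"] = 4
    group_sizes["ovary"] = 3
    group_sizes["testis"] = 3  # sums to 54
    baseline = {
        "RPS23": 19.2, "B2M": 19.7, "RPS9": 19.8, "EEF1A1": 20.0,
        "GAPDH": 20.3, "ACTB": 20.7, "RPL4": 20.8, "RPS15": 22.8,
        "UXT": 24.0, "HMBS": 25.5,
    }
    noise = {
        "RPS9": 0.20, "UXT": 0.25, "RPL4": 0.30, "RPS23": 0.30,
        "EEF1A1": 0.55, "ACTB": 0.70, "GAPDH": 0.75, "HMBS": 0.80,
        "B2M": 0.90, "RPS15": 1.90,
    }
    regulation = {
        ("B2M", "spleen"): 1.8,
        ("B2M", "liver"): 1.5,
        ("B2M", "intestine"): 1.5,
    }
    return SimConfig(
        genes=list(baseline),
        group_sizes=group_sizes,
        baseline_cq=baseline,
        noise_sd=noise,
        loading_sd=loading_sd,
        seed=seed,
        regulation=regulation,
        replicate_sd=replicate_sd,
    )
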