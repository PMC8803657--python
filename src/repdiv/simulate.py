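"""Synthetic murine TRB repertoire generator with known ground truth.

Junctions are assembled from per-segment nucleotide stubs (the CDR3 core a
segment contributes), with geometric exonuclease trimming at each joint and
Poisson-length N-insertions with configurable base bias.  Clone sizes come
from a configurable law (uniform / geometric / power-law / log-normal) and
are realized as UMI counts by multinomial sampling to the target depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from repdiv.errors import ConfigurationError, GenerationError
from repdiv.io_clonotypes import Clonotype, Repertoire, translate_nt

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_repertoire",
]

# V-segment CDR3 cores: conserved cysteine codon onward.
DEFAULT_V_STUBS = {
    "TRBV1": "TGTACCTGCAGTGCAGAC",
    "TRBV3": "TGTGCCAGCAGCTTAGAT",
    "TRBV4": "TGTGCCAGCAGCTATGAA",
    "TRBV12-2": "TGTGCCAGCTCTCTGGGC",
    "TRBV13-1": "TGTGCCAGCAGTGATGCC",
    "TRBV15": "TGTGCCAGCAGTTTCGAC",
    "TRBV16": "TGTGCAAGCAGCTTGGAA",
    "TRBV19": "TGTGCCAGCAGTATAGGT",
    "TRBV20": "TGTGGTGCTAGAGATCGA",
    "TRBV23": "TGTAGCAGTTCGCAAGGG",
    "TRBV29": "TGTGCCAGCAGCCTAAGC",
    "TRBV30": "TGTGCCTGGAGTCTGCAA",
    "TRBV31": "TGTGCCTGGAGTCTTCAG",
}
DEFAULT_V_WEIGHTS = {
    "TRBV1": 0.05, "TRBV3": 0.07, "TRBV4": 0.12, "TRBV12-2": 0.15,
    "TRBV13-1": 0.08, "TRBV15": 0.09, "TRBV16": 0.06, "TRBV19": 0.08,
    "TRBV20": 0.07, "TRBV23": 0.05, "TRBV29": 0.04, "TRBV30": 0.06,
    "TRBV31": 0.08,
}

DEFAULT_D_STUBS = {"TRBD1": "GGGACAGGGGGC", "TRBD2": "GGGACTGGGGGGGC"}
DEFAULT_D_WEIGHTS = {"TRBD1": 0.55, "TRBD2": 0.45}

# J-segment CDR3 cores: up to and including the conserved phenylalanine codon.
DEFAULT_J_STUBS = {
    "TRBJ1-1": "AACACAGAAGTCTTCTTC",
    "TRBJ1-3": "TCTGGAAATACGCTCTAT",  # + TTT appended below
    "TRBJ1-4": "TCCAACGAAAGATTATTT",
    "TRBJ1-5": "AACCAGGCTCCGCTTTTT",
    "TRBJ2-1": "AACTATGCTGAGCAGTTC",
    "TRBJ2-3": "AGTGCAGAAACGCTGTAT",  # + TTT appended below
    "TRBJ2-5": "AACCAAGACACCCAGTAC",  # + TTC appended below
    "TRBJ2-7": "TCCTATGAACAGTACTTC",
}
DEFAULT_J_STUBS["TRBJ1-3"] += "TTT"
DEFAULT_J_STUBS["TRBJ2-3"] += "TTT"
DEFAULT_J_STUBS["TRBJ2-5"] += "TTC"
DEFAULT_J_WEIGHTS = {
    "TRBJ1-1": 0.12, "TRBJ1-3": 0.10, "TRBJ1-4": 0.09, "TRBJ1-5": 0.11,
    "TRBJ2-1": 0.13, "TRBJ2-3": 0.12, "TRBJ2-5": 0.14, "TRBJ2-7": 0.19,
}

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"


def _validated_weights(weights: dict[str, float], what: str) -> dict[str, float]:
    if any(w < 0 for w in weights.values()):
        raise ConfigurationError(f"{what} usage weights must be nonnegative")
    total = sum(weights.values())
    if total <= 0:
        raise ConfigurationError(f"{what} usage weights sum to zero")
    return {g: w / total for g, w in weights.items()}


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic V(D)J generator."""

    seed: int = 0
    n_clonotypes: int = 200
    depth: int = 12000
    v_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_V_WEIGHTS))
    d_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_D_WEIGHTS))
    j_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_J_WEIGHTS))
    v_stubs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_V_STUBS))
    d_stubs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_D_STUBS))
    j_stubs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_J_STUBS))
    trim_mean: float = 2.0  # geometric trimming, mean per joint end
    insert_mean: float = 4.0  # Poisson N-insertion length per joint
    insert_base_weights: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    clone_size_law: str = "geometric"  # uniform | geometric | powerlaw | lognormal
    clone_size_params: dict[str, float] = field(default_factory=dict)
    productive_only: bool = True
    max_retries: int = 50

    def __post_init__(self):
        if self.n_clonotypes < 1 or self.depth < 1:
            raise ConfigurationError("n_clonotypes and depth must be >= 1")
        self.v_weights = _validated_weights(self.v_weights, "V")
        self.d_weights = _validated_weights(self.d_weights, "D")
        self.j_weights = _validated_weights(self.j_weights, "J")
        for g in self.v_weights:
            if g not in self.v_stubs:
                raise ConfigurationError(f"no stub for V gene {g}")
        for g in self.d_weights:
            if g not in self.d_stubs:
                raise ConfigurationError(f"no stub for D gene {g}")
        for g in self.j_weights:
            if g not in self.j_stubs:
                raise ConfigurationError(f"no stub for J gene {g}")


@dataclass
class GroundTruth:
    """What the generator actually used — for recovery tests."""

    true_richness: int
    clone_size_weights: np.ndarray
    v_weights: dict[str, float]
    d_weights: dict[str, float]
    j_weights: dict[str, float]
    clone_size_law: str
    clone_size_params: dict[str, float]
    seed: int


def _clone_size_weights(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_clonotypes
    law = cfg.clone_size_law
    p = cfg.clone_size_params
    if law == "uniform":
        w = np.ones(n)
    elif law == "geometric":
        ratio = 1.0 - p.get("p", 0.02)
        w = ratio ** np.arange(n)
    elif law == "powerlaw":
        a = p.get("exponent", 1.5)
        w = np.arange(1, n + 1, dtype=float) ** (-a)
    elif law == "lognormal":
        sigma = p.get("sigma", 1.5)
        w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    else:
        raise ConfigurationError(f"unknown clone_size_law {cfg.clone_size_law!r}")
    return w / w.sum()


def _geometric_trim(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def _insert(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    n = int(rng.poisson(cfg.insert_mean))
    if n == 0:
        return ""
    probs = np.asarray(cfg.insert_base_weights, dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(4, size=n, p=probs)
    return "".join(_BASES[i] for i in idx)


def _has_stop(nt: str) -> bool:
    return any(nt[i : i + 3] in _STOP_CODONS for i in range(0, len(nt) - 2, 3))


def _build_junction(cfg: SimulationConfig, rng: np.random.Generator,
                    genes: tuple[str, str, str]) -> str:
    v, d, j = genes
    vs, ds, js = cfg.v_stubs[v], cfg.d_stubs[d], cfg.j_stubs[j]
    # conserved C codon and J phenylalanine codon are protected from trimming
    v_keep = max(3, len(vs) - _geometric_trim(rng, cfg.trim_mean))
    j_keep = max(3, len(js) - _geometric_trim(rng, cfg.trim_mean))
    d5 = _geometric_trim(rng, cfg.trim_mean)
    d3 = _geometric_trim(rng, cfg.trim_mean)
    d_core = ds[min(d5, len(ds)) : max(0, len(ds) - d3)]
    return (
        vs[:v_keep]
        + _insert(rng, cfg)
        + d_core
        + _insert(rng, cfg)
        + js[len(js) - j_keep :]
    )


def simulate_repertoire(
    cfg: SimulationConfig,
    sample_id: str = "sim",
    group: str = "other",
    subset: str = "other",
    rng: np.random.Generator | None = None,
) -> tuple[Repertoire, GroundTruth]:
    """Generate one repertoire plus its ground truth; reproducible from seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    v_genes = list(cfg.v_weights)
    d_genes = list(cfg.d_weights)
    j_genes = list(cfg.j_weights)
    v_cum = np.cumsum([cfg.v_weights[g] for g in v_genes])
    d_cum = np.cumsum([cfg.d_weights[g] for g in d_genes])
    j_cum = np.cumsum([cfg.j_weights[g] for g in j_genes])

    seen_keys: set[tuple[str, str, str]] = set()
    proto: list[Clonotype] = []
    for _ in range(cfg.n_clonotypes):
        for attempt in range(cfg.max_retries + 1):
            if attempt == cfg.max_retries:
                raise GenerationError(
                    f"could not generate a valid clonotype in {cfg.max_retries} tries"
                )
            v = v_genes[int(np.searchsorted(v_cum, rng.random() * v_cum[-1]))]
            d = d_genes[int(np.searchsorted(d_cum, rng.random() * d_cum[-1]))]
            j = j_genes[int(np.searchsorted(j_cum, rng.random() * j_cum[-1]))]
            nt = _build_junction(cfg, rng, (v, d, j))
            productive = len(nt) % 3 == 0 and not _has_stop(nt)
            if cfg.productive_only and not productive:
                continue
            key = (nt, v, j)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            aa = translate_nt(nt) if len(nt) % 3 == 0 else ""
            proto.append(
                Clonotype(
                    cdr3_nt=nt, cdr3_aa=aa, v_gene=v, j_gene=j, d_gene=d,
                    count=1, productive=productive,
                )
            )
            break

    weights = _clone_size_weights(cfg, rng)
    counts = rng.multinomial(cfg.depth, weights)
    clonotypes = [
        dataclasses.replace(ct, count=int(c))
        for ct, c in zip(proto, counts)
        if c > 0
    ]
    rep = Repertoire.from_clonotypes(sample_id, clonotypes, group=group, subset=subset)
    truth = GroundTruth(
        true_richness=cfg.n_clonotypes,
        clone_size_weights=weights,
        v_weights=dict(cfg.v_weights),
        d_weights=dict(cfg.d_weights),
        j_weights=dict(cfg.j_weights),
        clone_size_law=cfg.clone_size_law,
        clone_size_params=dict(cfg.clone_size_params),
        seed=cfg.seed,
    )
    return rep, truth


def _apply_usage_effect(weights: dict[str, float], deltas: dict[str, float]) -> dict[str, float]:
    """Shift named genes by the given deltas; others shrink proportionally."""
    for g in deltas:
        if g not in weights:
            raise ConfigurationError(f"effect references unknown gene {g!r}")
    new = dict(weights)
    shift = 0.0
    for g, delta in deltas.items():
        target = new[g] + delta
        if target < 0:
            raise ConfigurationError(f"effect drives {g} usage below zero")
        shift += target - new[g]
        new[g] = target
    others = [g for g in new if g not in deltas]
    rest = sum(new[g] for g in others)
    if rest <= 0 and abs(shift) > 0:
        raise ConfigurationError("no probability mass left to absorb the usage effect")
    for g in others:
        new[g] *= (rest - shift) / rest
    total = sum(new.values())
    return {g: w / total for g, w in new.items()}


def _perturbed_config(cfg: SimulationConfig, effects: dict, seed: int) -> SimulationConfig:
    kwargs = dataclasses.asdict(cfg)
    kwargs["seed"] = seed
    for axis in ("v", "d", "j"):
        key = f"{axis}_usage"
        if key in effects:
            kwargs[f"{axis}_weights"] = _apply_usage_effect(
                kwargs[f"{axis}_weights"], effects[key]
            )
    for field_name in ("clone_size_law", "clone_size_params", "depth",
                       "n_clonotypes", "trim_mean", "insert_mean"):
        if field_name in effects:
            kwargs[field_name] = effects[field_name]
    unknown = set(effects) - {"v_usage", "d_usage", "j_usage", "clone_size_law",
                              "clone_size_params", "depth", "n_clonotypes",
                              "trim_mean", "insert_mean"}
    if unknown:
        raise ConfigurationError(f"unknown effect keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)


def simulate_cohort(
    base_cfg: SimulationConfig,
    n_samples_per_group: int,
    group_effects: dict[str, dict],
    subset: str = "other",
) -> tuple[list[Repertoire], dict]:
    """Simulate one repertoire cohort with per-group effect perturbations.

    ``group_effects`` maps group label to an effect dict ({} = no effect);
    per-sample seeds are derived deterministically from the base seed.
    Returns the repertoires plus a bookkeeping dict recording the effective
    per-group configurations for recovery tests.
    """
    if n_samples_per_group < 1:
        raise ConfigurationError("n_samples_per_group must be >= 1")
    ss = np.random.SeedSequence(base_cfg.seed)
    children = ss.spawn(len(group_effects) * n_samples_per_group)
    reps: list[Repertoire] = []
    bookkeeping: dict = {}
    i = 0
    for group, effects in group_effects.items():
        cfg_g = _perturbed_config(base_cfg, effects or {}, seed=base_cfg.seed)
        bookkeeping[group] = {
            "effects": dict(effects or {}),
            "v_weights": dict(cfg_g.v_weights),
            "clone_size_law": cfg_g.clone_size_law,
            "clone_size_params": dict(cfg_g.clone_size_params),
            "depth": cfg_g.depth,
            "n_clonotypes": cfg_g.n_clonotypes,
        }
        for s in range(n_samples_per_group):
            rng = np.random.default_rng(children[i])
            rep, _ = simulate_repertoire(
                cfg_g,
                sample_id=f"{group}_{s + 1}",
                group=group,
                subset=subset,
                rng=rng,
            )
            reps.append(rep)
            i += 1
    return reps, bookkeeping
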