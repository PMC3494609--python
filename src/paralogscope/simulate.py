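"""Synthetic fixtures with known ground truth.

Two generators: codon-sequence pairs evolved under a TN93-rate codon
process with a target synonymous divergence and omega, and expression
matrices with latent condition patterns and tunable within-pair similarity.
Both are fully reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evolution import GENETIC_CODE, STOP_CODONS, TS_AG, TS_CT, _change_type
from .io import CodingSequence, ExpressionTable, GenePairRecord

__all__ = [
    "SeqSimConfig",
    "SeqSimTruth",
    "ExprSimConfig",
    "ExprSimTruth",
    "simulate_codon_pair",
    "simulate_expression",
    "expression_pair_records",
]

_NUCLEOTIDES = "ACGT"
_SENSE_CODONS = sorted(GENETIC_CODE)
_MAX_BRANCH_S = 5.0  # beyond this, synonymous sites are hopelessly saturated


@dataclass(frozen=True)
class SeqSimConfig:
    """Parameters for one simulated coding-sequence pair."""

    n_codons: int = 300
    branch_length_s: float = 0.5  # target pairwise Ks
    omega_true: float = 0.3
    kappa_R: float = 4.0
    kappa_Y: float = 4.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.omega_true < 0:
            raise ValueError("omega_true must be nonnegative")
        if self.branch_length_s < 0 or self.branch_length_s >= _MAX_BRANCH_S:
            raise ValueError(
                f"branch_length_s must lie in [0, {_MAX_BRANCH_S}) "
                "(calibration unreachable beyond)"
            )
        if self.kappa_R <= 0 or self.kappa_Y <= 0:
            raise ValueError("kappas must be positive")
        if abs(sum(self.pi) - 1.0) > 1e-9 or min(self.pi) <= 0:
            raise ValueError("pi must be positive and sum to 1")


@dataclass(frozen=True)
class SeqSimTruth:
    omega_true: float
    branch_length_s: float
    t_total: float
    syn_events: int
    nonsyn_events: int
    syn_sites: float  # mutational-opportunity S of the ancestor
    nonsyn_sites: float

    @property
    def ks_realized(self) -> float:
        return self.syn_events / self.syn_sites

    @property
    def ka_realized(self) -> float:
        return self.nonsyn_events / self.nonsyn_sites


def _codon_rates(cfg: SeqSimConfig) -> dict[str, tuple[list[str], np.ndarray, np.ndarray]]:
    """Per-codon single-nucleotide step rates (targets, rates, is_synonymous)."""
    pi = dict(zip(_NUCLEOTIDES, (cfg.pi[0], cfg.pi[1], cfg.pi[2], cfg.pi[3])))
    table = {}
    for codon in _SENSE_CODONS:
        targets, rates, is_syn = [], [], []
        for pos in range(3):
            for alt in _NUCLEOTIDES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                t = _change_type(codon[pos], alt)
                k = cfg.kappa_R if t == TS_AG else cfg.kappa_Y if t == TS_CT else 1.0
                syn = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
                rate = pi[alt] * k * (1.0 if syn else cfg.omega_true)
                if rate > 0:
                    targets.append(mutant)
                    rates.append(rate)
                    is_syn.append(syn)
        table[codon] = (targets, np.asarray(rates), np.asarray(is_syn, dtype=bool))
    return table


def _opportunity_sites(codon: str, cfg: SeqSimConfig) -> float:
    """Synonymous sites of one codon: 3 x (syn mutation rate / total)."""
    pi = dict(zip(_NUCLEOTIDES, cfg.pi))
    syn_mu = tot_mu = 0.0
    for pos in range(3):
        for alt in _NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            t = _change_type(codon[pos], alt)
            k = cfg.kappa_R if t == TS_AG else cfg.kappa_Y if t == TS_CT else 1.0
            mu = pi[alt] * k  # mutation opportunity: no omega
            tot_mu += mu
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                syn_mu += mu
    return 3.0 * syn_mu / tot_mu


def simulate_codon_pair(
    cfg: SeqSimConfig,
) -> tuple[CodingSequence, CodingSequence, SeqSimTruth]:
    """Evolve two lineages from a random ancestor of sense codons.

    Single-nucleotide steps at TN93 relative rates with nonsynonymous steps
    multiplied by ``omega_true`` and stop codons forbidden.  Total time is
    calibrated so the expected pairwise synonymous divergence per synonymous
    site equals ``branch_length_s``.
    """
    rng = np.random.default_rng(cfg.seed)
    pi = np.asarray(cfg.pi)

    ancestor = []
    while len(ancestor) < cfg.n_codons:
        codon = "".join(rng.choice(list(_NUCLEOTIDES), size=3, p=pi))
        if codon not in STOP_CODONS:
            ancestor.append(codon)

    s_sites = sum(_opportunity_sites(c, cfg) for c in ancestor)
    n_sites = 3.0 * cfg.n_codons - s_sites
    rates = _codon_rates(cfg)
    syn_rate_total = sum(rates[c][1][rates[c][2]].sum() for c in ancestor)
    if syn_rate_total <= 0:
        raise ValueError("no synonymous substitution opportunity in ancestor")
    t_total = cfg.branch_length_s * s_sites / syn_rate_total

    def evolve(codon: str, t: float) -> tuple[str, int, int]:
        syn_events = nonsyn_events = 0
        remaining = t
        while True:
            targets, r, is_syn = rates[codon]
            total = r.sum()
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            if dt > remaining:
                break
            remaining -= dt
            j = int(np.searchsorted(np.cumsum(r), rng.uniform(0, total), side="right"))
            j = min(j, len(targets) - 1)
            if is_syn[j]:
                syn_events += 1
            else:
                nonsyn_events += 1
            codon = targets[j]
        return codon, syn_events, nonsyn_events

    seqs = []
    syn_total = nonsyn_total = 0
    for _ in range(2):
        lineage = []
        for codon in ancestor:
            end, s_ev, n_ev = evolve(codon, t_total / 2.0)
            lineage.append(end)
            syn_total += s_ev
            nonsyn_total += n_ev
        seqs.append("".join(lineage))

    truth = SeqSimTruth(
        omega_true=cfg.omega_true,
        branch_length_s=cfg.branch_length_s,
        t_total=t_total,
        syn_events=syn_total,
        nonsyn_events=nonsyn_total,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
    )
    return (
        CodingSequence("sim1", seqs[0]),
        CodingSequence("sim2", seqs[1]),
        truth,
    )


# ---------------------------------------------------------------------------
# Expression simulation


@dataclass(frozen=True)
class ExprSimConfig:
    """Parameters for a simulated paired expression matrix."""

    n_pairs: int = 200
    n_conditions: int = 7
    n_replicates: int = 3
    n_patterns: int = 16
    within_pair_cosine: float = 0.95
    noise_sd: float = 0.1
    max_pattern_cosine: float = 0.75  # rejection bound between latent patterns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need >= 2 conditions")
        if not 1 <= self.n_patterns <= self.n_pairs:
            raise ValueError("n_patterns must lie in [1, n_pairs]")
        if not 0.0 <= self.within_pair_cosine <= 1.0:
            raise ValueError("within_pair_cosine must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class ExprSimTruth:
    pattern_labels: list[int]  # per pair
    classes: list[str]  # per pair, alternating in/out
    pair_cosines_raw: list[float]  # of the noise-free latent profiles
    pair_cosines_realized: list[float] = field(default_factory=list)  # post averaging+z-scoring


def _centered_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        v = rng.standard_normal(n)
        v -= v.mean()
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm


def _draw_patterns(rng: np.random.Generator, cfg: ExprSimConfig) -> np.ndarray:
    patterns: list[np.ndarray] = []
    attempts = 0
    while len(patterns) < cfg.n_patterns:
        candidate = _centered_unit(rng, cfg.n_conditions)
        if all(abs(candidate @ p) <= cfg.max_pattern_cosine for p in patterns):
            patterns.append(candidate)
        attempts += 1
        if attempts > 100_000:
            raise ValueError(
                "could not draw sufficiently decorrelated patterns; "
                "lower n_patterns or raise max_pattern_cosine"
            )
    return np.vstack(patterns)


def simulate_expression(cfg: ExprSimConfig) -> tuple[ExpressionTable, ExprSimTruth]:
    """Generate a replicate expression table with latent pair structure.

    Each pair's first copy follows a latent zero-mean unit pattern; the
    second copy sits at angle ``arccos(within_pair_cosine)`` from it within
    a random plane.  Replicate values add homoscedastic Gaussian noise.
    The truth record carries pattern labels, alternating in/out classes,
    and the realized post-normalization pair cosines.
    """
    rng = np.random.default_rng(cfg.seed)
    patterns = _draw_patterns(rng, cfg)

    gene_ids: list[str] = []
    profiles: list[np.ndarray] = []
    labels: list[int] = []
    classes: list[str] = []
    raw_cosines: list[float] = []
    wpc = cfg.within_pair_cosine
    for i in range(cfg.n_pairs):
        label = i % cfg.n_patterns
        u = patterns[label]
        w = _centered_unit(rng, cfg.n_conditions)
        w -= (w @ u) * u
        norm = np.linalg.norm(w)
        while norm < 1e-8:  # redraw a perpendicular direction
            w = _centered_unit(rng, cfg.n_conditions)
            w -= (w @ u) * u
            norm = np.linalg.norm(w)
        v = wpc * u + math.sqrt(max(0.0, 1.0 - wpc * wpc)) * (w / norm)
        gene_ids.extend([f"pair{i + 1:03d}_a", f"pair{i + 1:03d}_b"])
        profiles.extend([u, v])
        labels.append(label)
        classes.append("in" if i % 2 == 0 else "out")
        raw_cosines.append(float(u @ v))

    base = np.vstack(profiles)  # (2 * n_pairs, n_conditions)
    values = (
        base[:, :, None]
        + rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), cfg.n_conditions, cfg.n_replicates))
        if cfg.noise_sd > 0
        else np.repeat(base[:, :, None], cfg.n_replicates, axis=2)
    )
    conditions = [f"cond{j + 1}" for j in range(cfg.n_conditions)]
    table = ExpressionTable(gene_ids, conditions, values)

    averaged = values.mean(axis=2)
    realized = []
    for i in range(cfg.n_pairs):
        a, b = averaged[2 * i], averaged[2 * i + 1]
        za = a - a.mean()
        zb = b - b.mean()
        sa, sb = np.linalg.norm(za), np.linalg.norm(zb)
        realized.append(float(za @ zb / (sa * sb)) if sa > 0 and sb > 0 else math.nan)

    truth = ExprSimTruth(labels, classes, raw_cosines, realized)
    return table, truth


def expression_pair_records(
    truth: ExprSimTruth, divergence: Optional[list[float]] = None
) -> list[GenePairRecord]:
    """Pair records matching :func:`simulate_expression` gene naming.

    Replicons are placeholder CI/CI; optional per-pair amino-acid
    divergences enable quadrant classification downstream.
    """
    records = []
    for i, cls in enumerate(truth.classes):
        records.append(
            GenePairRecord(
                gene1_id=f"pair{i + 1:03d}_a",
                gene2_id=f"pair{i + 1:03d}_b",
                paralog_class=cls,
                replicon1="CI",
                replicon2="CI",
                divergence_pct=divergence[i] if divergence else None,
            )
        )
    return records
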