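"""Pairwise Ka/Ks estimation for coding sequences.

The estimation chain mirrors the classic five steps: translate both coding
sequences, align the proteins globally, back-translate the alignment onto
the original codons, then estimate synonymous (Ks) and nonsynonymous (Ka)
substitution rates.  Three estimators are provided:

* ``NG86`` — equal-weight site counting with Jukes–Cantor correction; serves
  as the internal oracle for the weighted estimators.
* ``MYN`` — sites and differences weighted under the Tamura–Nei (TN93)
  substitution model with distinct purine (kappa_R) and pyrimidine
  (kappa_Y) transition/transversion rate ratios.
* ``gMYN`` — MYN with every multiple-hit log correction replaced by its
  gamma-rates analogue ``alpha * (x**(-1/alpha) - 1)``.

Saturation (a correction argument falling to or below zero) is reported as
a typed state on the estimate, never as a negative rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io import CodingSequence

__all__ = [
    "ProteinAlignment",
    "CodonAlignment",
    "Tn93Params",
    "DiffSummary",
    "SubstitutionEstimate",
    "STOP_CODONS",
    "GENETIC_CODE",
    "translate_codons",
    "align_protein_pair",
    "build_codon_alignment",
    "amino_acid_divergence",
    "estimate_tn93_params",
    "tn93_distance",
    "ng86_kaks",
    "myn_kaks",
    "gamma_myn_kaks",
    "pair_kaks_pipeline",
    "count_pathway_differences",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
GENETIC_CODE = dict(_STANDARD.forward_table)  # 61 sense codons -> amino acid

_NUCLEOTIDES = "ACGT"
_KAPPA_FLOOR = 1e-4
_PI_FLOOR = 1e-4

# Substitution-type keys: A<->G transitions, C<->T transitions, transversions.
TS_AG, TS_CT, TV = "AG", "CT", "TV"


class TranslationError(ValueError):
    """Internal stop codon or other frame problem in a CDS."""


class AlignmentError(ValueError):
    """Invalid alignment input or protein/DNA inconsistency."""


def _change_type(a: str, b: str) -> str:
    pair = frozenset((a, b))
    if pair == frozenset("AG"):
        return TS_AG
    if pair == frozenset("CT"):
        return TS_CT
    return TV


# ---------------------------------------------------------------------------
# Translation / alignment


def translate_codons(seq: CodingSequence) -> str:
    """Translate a CDS with the standard genetic code (table 1).

    A single terminal stop codon is stripped; an internal stop raises
    :class:`TranslationError` naming the 1-based codon index.
    """
    codons = seq.codons()
    aas = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i == len(codons) - 1:
                break
            raise TranslationError(
                f"sequence {seq.gene_id!r}: internal stop codon {codon} "
                f"at codon {i + 1}"
            )
        aas.append(GENETIC_CODE[codon])
    if not aas:
        raise TranslationError(f"sequence {seq.gene_id!r}: no coding codons")
    return "".join(aas)


@dataclass(frozen=True)
class ProteinAlignment:
    """A global pairwise protein alignment (equal-length gapped strings)."""

    aligned1: str
    aligned2: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned1) != len(self.aligned2):
            raise AlignmentError("aligned strings differ in length")
        if any(a == "-" == b for a, b in zip(self.aligned1, self.aligned2)):
            raise AlignmentError("gap-vs-gap column in alignment")


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    # A gap of length k costs gap_open + k * gap_extend (half-bit units).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_protein_pair(
    p1: str, p2: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> ProteinAlignment:
    """Optimal end-to-end global alignment under BLOSUM62 with affine gaps.

    Deterministic: the aligner's first optimal traceback is taken.
    """
    if not p1 or not p2:
        raise AlignmentError("cannot align an empty protein sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = next(iter(aligner.align(p1, p2)))
    return ProteinAlignment(str(alignment[0]), str(alignment[1]), alignment.score)


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns derived from a protein alignment."""

    codon_columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for c1, c2 in self.codon_columns:
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                raise AlignmentError(f"stop codon in alignment column ({c1}, {c2})")

    def __len__(self) -> int:
        return len(self.codon_columns)

    def concatenated(self) -> tuple[str, str]:
        return (
            "".join(c1 for c1, _ in self.codon_columns),
            "".join(c2 for _, c2 in self.codon_columns),
        )


def build_codon_alignment(
    aln: ProteinAlignment, dna1: CodingSequence, dna2: CodingSequence
) -> CodonAlignment:
    """Back-translate a protein alignment onto the original codons.

    Columns with a gap in either row are dropped; codon order is preserved.
    The ungapped protein rows must equal the translations of the CDSs.
    """
    for which, (row, dna) in enumerate(
        [(aln.aligned1, dna1), (aln.aligned2, dna2)], start=1
    ):
        ungapped = row.replace("-", "")
        protein = translate_codons(dna)
        if ungapped != protein:
            pos = next(
                (i for i, (a, b) in enumerate(zip(ungapped, protein)) if a != b),
                min(len(ungapped), len(protein)),
            )
            raise AlignmentError(
                f"protein row {which} does not match translation of "
                f"{dna.gene_id!r} (first mismatch at residue {pos + 1})"
            )
    codons1, codons2 = dna1.codons(), dna2.codons()
    i1 = i2 = 0
    columns = []
    for a, b in zip(aln.aligned1, aln.aligned2):
        if a != "-" and b != "-":
            c1, c2 = codons1[i1], codons2[i2]
            if c1 not in STOP_CODONS and c2 not in STOP_CODONS:
                columns.append((c1, c2))
        if a != "-":
            i1 += 1
        if b != "-":
            i2 += 1
    return CodonAlignment(tuple(columns))


def amino_acid_divergence(aln: ProteinAlignment) -> float:
    """Percent mismatching residues over columns where both rows have one."""
    both = [
        (a, b)
        for a, b in zip(aln.aligned1, aln.aligned2)
        if a != "-" and b != "-"
    ]
    if not both:
        raise AlignmentError("no gap-free columns; divergence undefined")
    mismatches = sum(a != b for a, b in both)
    return 100.0 * mismatches / len(both)


# ---------------------------------------------------------------------------
# TN93 machinery


@dataclass(frozen=True)
class Tn93Params:
    """Tamura–Nei model parameters (frequencies, two kappas, gamma shape)."""

    pi_A: float
    pi_C: float
    pi_G: float
    pi_T: float
    kappa_R: float
    kappa_Y: float
    gamma_shape: Optional[float] = None

    def __post_init__(self) -> None:
        pis = (self.pi_A, self.pi_C, self.pi_G, self.pi_T)
        if not all(0 < p < 1 for p in pis) or abs(sum(pis) - 1.0) > 1e-9:
            raise ValueError(f"invalid frequencies {pis}")
        if self.kappa_R <= 0 or self.kappa_Y <= 0:
            raise ValueError("kappas must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def pi(self) -> dict[str, float]:
        return {"A": self.pi_A, "C": self.pi_C, "G": self.pi_G, "T": self.pi_T}

    @property
    def pi_R(self) -> float:
        return self.pi_A + self.pi_G

    @property
    def pi_Y(self) -> float:
        return self.pi_C + self.pi_T

    def with_gamma(self, gamma_shape: Optional[float]) -> "Tn93Params":
        return Tn93Params(
            self.pi_A, self.pi_C, self.pi_G, self.pi_T,
            self.kappa_R, self.kappa_Y, gamma_shape,
        )


@dataclass(frozen=True)
class DiffSummary:
    """Observed difference proportions feeding the TN93 correction."""

    p1: float  # A<->G transitional differences per site
    p2: float  # C<->T transitional differences per site
    q: float  # transversional differences per site
    n_sites: int

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.q) < 0:
            raise ValueError("difference proportions must be nonnegative")


def _tn93_arguments(d: DiffSummary, params: Tn93Params) -> tuple[float, float, float]:
    pi_R, pi_Y = params.pi_R, params.pi_Y
    w1 = 1.0 - pi_R * d.p1 / (2.0 * params.pi_A * params.pi_G) - d.q / (2.0 * pi_R)
    w2 = 1.0 - pi_Y * d.p2 / (2.0 * params.pi_C * params.pi_T) - d.q / (2.0 * pi_Y)
    w3 = 1.0 - d.q / (2.0 * pi_R * pi_Y)
    return w1, w2, w3


def tn93_distance(d: DiffSummary, params: Tn93Params) -> Optional[float]:
    """Multiple-hit-corrected TN93 distance, or ``None`` when saturated.

    With ``params.gamma_shape`` set, each ``-ln(x)`` correction is replaced
    by ``alpha * (x**(-1/alpha) - 1)`` (gamma-distributed rates across
    sites); the limit ``alpha -> inf`` recovers the uniform-rate formula.
    """
    w1, w2, w3 = _tn93_arguments(d, params)
    if min(w1, w2, w3) <= 0.0:
        return None
    alpha = params.gamma_shape
    if alpha is None:
        a1, a2, b = -math.log(w1), -math.log(w2), -math.log(w3)
    else:
        a1 = alpha * (w1 ** (-1.0 / alpha) - 1.0)
        a2 = alpha * (w2 ** (-1.0 / alpha) - 1.0)
        b = alpha * (w3 ** (-1.0 / alpha) - 1.0)
    pi_R, pi_Y = params.pi_R, params.pi_Y
    dist = (
        (2.0 * params.pi_A * params.pi_G / pi_R) * (a1 - pi_Y * b)
        + (2.0 * params.pi_C * params.pi_T / pi_Y) * (a2 - pi_R * b)
        + 2.0 * pi_R * pi_Y * b
    )
    return max(dist, 0.0)


def _observed_differences(seq1: str, seq2: str) -> tuple[float, float, float, int]:
    n = len(seq1)
    c1 = c2 = cq = 0
    for a, b in zip(seq1, seq2):
        if a == b:
            continue
        t = _change_type(a, b)
        if t == TS_AG:
            c1 += 1
        elif t == TS_CT:
            c2 += 1
        else:
            cq += 1
    return c1 / n, c2 / n, cq / n, n


def estimate_tn93_params(ca: CodonAlignment) -> Tn93Params:
    """Estimate TN93 frequencies and kappas from a codon alignment.

    Frequencies are pooled observed nucleotide frequencies over both
    sequences (floored and renormalized so all are positive).  kappa_R and
    kappa_Y are moment estimates from TN93-corrected transition and
    transversion distances over all aligned positions; with no observed
    differences both fall back to 1, and all outputs are floored positive.
    """
    if len(ca) < 1:
        raise AlignmentError("empty codon alignment")
    seq1, seq2 = ca.concatenated()
    pooled = seq1 + seq2
    counts = {nt: max(pooled.count(nt) / len(pooled), _PI_FLOOR) for nt in _NUCLEOTIDES}
    total = sum(counts.values())
    pi = {nt: c / total for nt, c in counts.items()}

    p1, p2, q, n = _observed_differences(seq1, seq2)
    if p1 + p2 + q == 0.0:
        return Tn93Params(pi["A"], pi["C"], pi["G"], pi["T"], 1.0, 1.0)

    base = Tn93Params(pi["A"], pi["C"], pi["G"], pi["T"], 1.0, 1.0)
    # half-count floor keeps the transversion distance positive when Q = 0
    q_eff = q if q > 0 else 0.5 / n
    d_eff = DiffSummary(p1, p2, q_eff, n)
    w1, w2, w3 = _tn93_arguments(d_eff, base)
    pi_R, pi_Y = base.pi_R, base.pi_Y
    if min(w1, w2, w3) > 0.0:
        a1, a2, b = -math.log(w1), -math.log(w2), -math.log(w3)
        d_ag = (2.0 * pi["A"] * pi["G"] / pi_R) * (a1 - pi_Y * b)
        d_ct = (2.0 * pi["C"] * pi["T"] / pi_Y) * (a2 - pi_R * b)
        d_tv = 2.0 * pi_R * pi_Y * b
    else:
        # saturated correction: fall back to uncorrected proportions
        d_ag, d_ct, d_tv = p1, p2, q_eff
    kappa_R = (d_ag / (2.0 * pi["A"] * pi["G"])) / (d_tv / (2.0 * pi_R * pi_Y))
    kappa_Y = (d_ct / (2.0 * pi["C"] * pi["T"])) / (d_tv / (2.0 * pi_R * pi_Y))
    return Tn93Params(
        pi["A"], pi["C"], pi["G"], pi["T"],
        max(kappa_R, _KAPPA_FLOOR), max(kappa_Y, _KAPPA_FLOOR),
    )


# ---------------------------------------------------------------------------
# Site counting and pathway-averaged difference counting


@lru_cache(maxsize=None)
def _site_fractions(codon: str, kappa_R: float, kappa_Y: float,
                    pi_A: float, pi_C: float, pi_G: float, pi_T: float) -> tuple[float, ...]:
    """Synonymous fraction of each codon position.

    Each one-step change is weighted by the target-nucleotide frequency
    times its transition-class rate; changes creating a stop codon are
    excluded from the opportunity set.
    """
    pi = {"A": pi_A, "C": pi_C, "G": pi_G, "T": pi_T}
    aa = GENETIC_CODE[codon]
    fractions = []
    for pos in range(3):
        syn_w = tot_w = 0.0
        for alt in _NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            t = _change_type(codon[pos], alt)
            k = kappa_R if t == TS_AG else kappa_Y if t == TS_CT else 1.0
            w = pi[alt] * k
            tot_w += w
            if GENETIC_CODE[mutant] == aa:
                syn_w += w
        fractions.append(syn_w / tot_w if tot_w > 0 else 0.0)
    return tuple(fractions)


def _count_sites(ca: CodonAlignment, params: Tn93Params) -> tuple[float, float]:
    """(S, N) averaged over the two sequences; S + N = 3 * len(ca)."""
    key = (params.kappa_R, params.kappa_Y,
           params.pi_A, params.pi_C, params.pi_G, params.pi_T)
    s_tot = 0.0
    for c1, c2 in ca.codon_columns:
        s_tot += sum(_site_fractions(c1, *key)) + sum(_site_fractions(c2, *key))
    s = s_tot / 2.0
    return s, 3.0 * len(ca) - s


@lru_cache(maxsize=None)
def count_pathway_differences(c1: str, c2: str) -> dict:
    """Average substitution counts over all minimal pathways c1 -> c2.

    Pathways change one differing position per step; intermediates that are
    stop codons are excluded (unless no stop-free pathway exists, in which
    case all pathways count and stop-involving steps are nonsynonymous).
    Returns ``{"syn": {AG, CT, TV}, "nonsyn": {AG, CT, TV}}`` averages.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    zero = {TS_AG: 0.0, TS_CT: 0.0, TV: 0.0}
    result = {"syn": dict(zero), "nonsyn": dict(zero)}
    if not diff:
        return result

    def walk(allow_stops: bool):
        paths = []

        def rec(cur, remaining, steps):
            if not remaining:
                paths.append(steps)
                return
            for pos in remaining:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not allow_stops and len(remaining) > 1:
                    continue
                if nxt in STOP_CODONS and len(remaining) == 1:
                    # endpoint stop cannot happen (alignment excludes stops)
                    continue
                rec(nxt, tuple(p for p in remaining if p != pos),
                    steps + ((cur, nxt, pos),))

        rec(c1, tuple(diff), ())
        return paths

    paths = walk(allow_stops=False) or walk(allow_stops=True)
    for path in paths:
        for cur, nxt, pos in path:
            t = _change_type(cur[pos], nxt[pos])
            synonymous = (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
            )
            result["syn" if synonymous else "nonsyn"][t] += 1.0 / len(paths)
    return result


def _count_differences(ca: CodonAlignment) -> tuple[dict, dict]:
    syn = {TS_AG: 0.0, TS_CT: 0.0, TV: 0.0}
    nonsyn = {TS_AG: 0.0, TS_CT: 0.0, TV: 0.0}
    for c1, c2 in ca.codon_columns:
        counts = count_pathway_differences(c1, c2)
        for t in (TS_AG, TS_CT, TV):
            syn[t] += counts["syn"][t]
            nonsyn[t] += counts["nonsyn"][t]
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Estimators


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Sites, differences, and corrected rates for one sequence pair.

    ``ka``/``ks`` are ``None`` when the corresponding correction saturated;
    ``omega`` is ``None`` when undefined (ks = 0 or saturation).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    ka: Optional[float]
    ks: Optional[float]
    omega: Optional[float]
    method: str
    params: Tn93Params
    saturated: bool = False


def _finish(S, N, Sd, Nd, ka, ks, method, params) -> SubstitutionEstimate:
    saturated = ka is None or ks is None
    omega = None
    if not saturated and ks > 0:
        omega = ka / ks
    return SubstitutionEstimate(S, N, Sd, Nd, ka, ks, omega, method, params, saturated)


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


_UNIFORM = Tn93Params(0.25, 0.25, 0.25, 0.25, 1.0, 1.0)


def ng86_kaks(ca: CodonAlignment) -> SubstitutionEstimate:
    """Unweighted-sites Ka/Ks with Jukes–Cantor correction.

    S and N come from the per-position synonymous fraction of one-step
    changes (stop-codon changes excluded); Sd and Nd from averaging over
    all minimal substitution pathways between differing codons.
    """
    if len(ca) < 2:
        raise AlignmentError("need at least 2 codon columns")
    S, N = _count_sites(ca, _UNIFORM)
    syn, nonsyn = _count_differences(ca)
    Sd, Nd = sum(syn.values()), sum(nonsyn.values())
    ks = _jc_correct(Sd / S) if S > 0 else None
    ka = _jc_correct(Nd / N) if N > 0 else None
    return _finish(S, N, Sd, Nd, ka, ks, "NG86", _UNIFORM)


def myn_kaks(
    ca: CodonAlignment,
    params: Optional[Tn93Params] = None,
    gamma_shape: Optional[float] = None,
    method: str = "MYN",
) -> SubstitutionEstimate:
    """TN93-weighted Ka/Ks.

    Three weighted steps: estimate TN93 parameters from the alignment,
    count S and N with each position's synonymous fraction weighted by the
    TN93 relative rates, then split the pathway-averaged differences into
    A<->G / C<->T transitional and transversional proportions at synonymous
    and nonsynonymous sites and correct each class with
    :func:`tn93_distance`.  Pass ``params`` to override the model estimate
    (e.g. to force the unbiased uniform limit).
    """
    if len(ca) < 2:
        raise AlignmentError("need at least 2 codon columns")
    if params is None:
        params = estimate_tn93_params(ca)
    params = params.with_gamma(gamma_shape)
    S, N = _count_sites(ca, params)
    syn, nonsyn = _count_differences(ca)
    Sd, Nd = sum(syn.values()), sum(nonsyn.values())
    n_sites = 3 * len(ca)
    ks = ka = None
    if S > 0 and Sd / S < 1.0:
        ks = tn93_distance(
            DiffSummary(syn[TS_AG] / S, syn[TS_CT] / S, syn[TV] / S, n_sites), params
        )
    if N > 0 and Nd / N < 1.0:
        ka = tn93_distance(
            DiffSummary(nonsyn[TS_AG] / N, nonsyn[TS_CT] / N, nonsyn[TV] / N, n_sites),
            params,
        )
    return _finish(S, N, Sd, Nd, ka, ks, method, params)


def gamma_myn_kaks(
    ca: CodonAlignment,
    gamma_shape: float = 1.0,
    params: Optional[Tn93Params] = None,
) -> SubstitutionEstimate:
    """MYN with gamma-rates multiple-hit corrections (method tag ``gMYN``)."""
    if gamma_shape is None or gamma_shape <= 0:
        raise ValueError("gamma_shape must be positive")
    return myn_kaks(ca, params=params, gamma_shape=gamma_shape, method="gMYN")


def pair_kaks_pipeline(
    dna1: CodingSequence,
    dna2: CodingSequence,
    method: str = "gMYN",
    gamma_shape: float = 1.0,
) -> tuple[SubstitutionEstimate, float]:
    """Translate, align, back-translate, and estimate for one gene pair.

    Returns the substitution estimate together with the percent amino-acid
    divergence of the protein alignment.
    """
    p1, p2 = translate_codons(dna1), translate_codons(dna2)
    aln = align_protein_pair(p1, p2)
    divergence = amino_acid_divergence(aln)
    ca = build_codon_alignment(aln, dna1, dna2)
    if method == "NG86":
        estimate = ng86_kaks(ca)
    elif method == "MYN":
        estimate = myn_kaks(ca)
    elif method == "gMYN":
        estimate = gamma_myn_kaks(ca, gamma_shape=gamma_shape)
    else:
        raise ValueError(f"unknown method {method!r}")
    return estimate, divergence
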