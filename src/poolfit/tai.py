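"""tRNA Adaptation Index: wobble-penalized adaptiveness weights and gene scoring.

For each sense codon the absolute adaptiveness W sums the gene copy numbers
(tGCN) of the cognate Watson-Crick anticodon and of the one wobble anticodon
able to read the codon, each discounted by a selective constraint s in [0,1]
(s = 0: pairing as efficient as Watson-Crick; s = 1: pairing useless):

    codon NNT:  W = (1-s1)*tGCN(A34) + (1-s5)*tGCN(G34)      (G:U wobble)
    codon NNC:  W = (1-s2)*tGCN(G34) + (1-s6)*tGCN(A34)      (A34 read as inosine, I:C)
    codon NNA:  W = (1-s3)*tGCN(T34) + (1-s7)*tGCN(A34)      (I:A)
    codon NNG:  W = (1-s4)*tGCN(C34) + (1-s8)*tGCN(T34)      (U:G wobble)

where X34 is the anticodon with wobble base X followed by the reverse
complement of codon positions 2 and 1.  In prokaryote mode ATA is read by the
lysidine-modified CAT-anticodon Ile2 tRNA, W(ATA) = (1-s9)*tGCN(CAT), and ATG
keeps only its Watson-Crick CAT term.  Relative adaptiveness is w = W/max(W),
with zero-W codons imputed as the geometric mean of the non-zero w values.
A gene's tAI is the geometric mean of w over its codons (stop codons, and by
default ATG, excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import CodonCounts
from .trna import TgcnVector

_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS: frozenset[str] = frozenset(_BACTERIAL.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_BACTERIAL.forward_table))
#: anticodons read off a gene, 5'->3': reverse complements of the sense codons
ANTICODONS: tuple[str, ...] = tuple(sorted(str(Seq(c).reverse_complement()) for c in SENSE_CODONS))

DEFAULT_EXCLUSIONS: frozenset[str] = STOP_CODONS | {"ATG"}

#: selective constraints of the reference tAI formulation, indexed s1..s9:
#: (WC U, WC C, WC A, WC G, G:U, I:C, I:A, U:G, lysidine ATA)
DEFAULT_S = (0.0, 0.0, 0.0, 0.0, 0.41, 0.28, 0.9999, 0.68, 0.89)

# codon third base -> ((wobble-base-34 of WC anticodon, s index), (wobble partner, s index))
_PAIRING: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {
    "T": (("A", 0), ("G", 4)),
    "C": (("G", 1), ("A", 5)),
    "A": (("T", 2), ("A", 6)),
    "G": (("C", 3), ("T", 7)),
}


class DegeneratePoolError(ValueError):
    """The tRNA pool gives every codon zero adaptiveness."""


class EmptyGeneError(ValueError):
    """No codon of the gene survives the exclusion set."""


@dataclass(frozen=True)
class WobbleParams:
    s: tuple[float, ...] = DEFAULT_S
    prokaryote_mode: bool = True

    def __post_init__(self):
        if len(self.s) != 9:
            raise ValueError("s must have 9 entries (s1..s9)")
        if any(not 0.0 <= x <= 1.0 for x in self.s):
            raise ValueError("each s must lie in [0, 1]")


@dataclass
class AdaptivenessWeights:
    W: dict[str, float]
    w: dict[str, float]
    zero_substituted: frozenset[str] = frozenset()
    pool_origin: str = ""


@dataclass(frozen=True)
class TaiResult:
    gene_id: str
    pool_origin: str
    tai: float
    codons_used: int
    zero_substituted_used: int = 0  # scored codons whose w was imputed


def _anticodon(codon: str, base34: str) -> str:
    """Anticodon with the given wobble (34) base reading this codon's first two positions."""
    return base34 + str(Seq(codon[:2]).reverse_complement())


def absolute_adaptiveness(pool: TgcnVector, params: WobbleParams | None = None) -> dict[str, float]:
    """Absolute adaptiveness W for every sense codon under the wobble rules above."""
    params = params or WobbleParams()
    s = params.s
    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        if params.prokaryote_mode and codon == "ATA":
            W[codon] = (1.0 - s[8]) * pool["CAT"]
            continue
        if params.prokaryote_mode and codon == "ATG":
            W[codon] = (1.0 - s[3]) * pool["CAT"]
            continue
        (wc_base, wc_idx), (wob_base, wob_idx) = _PAIRING[codon[2]]
        W[codon] = (1.0 - s[wc_idx]) * pool[_anticodon(codon, wc_base)] + (
            1.0 - s[wob_idx]
        ) * pool[_anticodon(codon, wob_base)]
    return W


def relative_adaptiveness(
    W: dict[str, float], pool_origin: str = ""
) -> AdaptivenessWeights:
    """w = W / max(W); zero-w codons are imputed with the geometric mean of non-zero w."""
    wmax = max(W.values())
    if wmax <= 0.0:
        raise DegeneratePoolError("all absolute adaptiveness values are zero")
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0.0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    zero = frozenset(c for c, v in w.items() if v == 0.0)
    for c in zero:
        w[c] = gm
    return AdaptivenessWeights(W=dict(W), w=w, zero_substituted=zero, pool_origin=pool_origin)


def pool_weights(pool: TgcnVector, params: WobbleParams | None = None) -> AdaptivenessWeights:
    """Convenience: absolute then relative adaptiveness for one pool."""
    return relative_adaptiveness(absolute_adaptiveness(pool, params), pool_origin=pool.origin)


def gene_tai(
    counts: CodonCounts,
    weights: AdaptivenessWeights,
    exclusions: frozenset[str] = DEFAULT_EXCLUSIONS,
) -> TaiResult:
    """tAI = exp( sum n_c ln w_c / sum n_c ) over codons not in the exclusion set."""
    log_sum = 0.0
    n = 0
    n_imputed = 0
    for codon, count in counts.counts.items():
        if codon in exclusions or codon in STOP_CODONS:
            continue
        log_sum += count * math.log(weights.w[codon])
        n += count
        if codon in weights.zero_substituted:
            n_imputed += count
    if n == 0:
        raise EmptyGeneError(f"{counts.gene_id or '<gene>'}: no scorable codons")
    return TaiResult(
        gene_id=counts.gene_id,
        pool_origin=weights.pool_origin,
        tai=math.exp(log_sum / n),
        codons_used=n,
        zero_substituted_used=n_imputed,
    )
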