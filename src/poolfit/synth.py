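"""Synthetic phage/host panels with controlled tRNA pools and codon-usage adaptation.

The generator emulates the statistical structure of the satellite-helper
study system: phages carrying ~40 tRNA genes, hosts whose tRNA pools are
GC-skewed relative to the phages' (actinobacterial hosts near 71% GC versus
phages near 49%), and a focal structural gene (the major capsid protein)
whose synonymous-codon choice is biased toward a designated pool with a
single adaptation strength t:

    P(codon c | amino acid) ∝ w_c^t

so t = 0 gives uniform synonymous choice, and t → ∞ always picks the
family's best-adapted codon.  Predictor-output views with coordinate jitter,
undetermined calls and missed calls exercise the reconciliation rules.
All draws flow from one numpy Generator, so panels are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from .compare import PairEntry, PairManifest
from .seqio import FeatureRecord, GenomeRecord
from .tai import ANTICODONS, AdaptivenessWeights, SENSE_CODONS, WobbleParams, pool_weights
from .trna import UNKNOWN, TgcnVector, TrnaGene, build_tgcn

_FWD = CodonTable.unambiguous_dna_by_id[11].forward_table
#: amino acid -> synonymous codon family (bacterial code)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(_FWD[_codon], tuple())
FAMILIES = {aa: tuple(c for c in SENSE_CODONS if _FWD[c] == aa) for aa in FAMILIES}
_AA = tuple(sorted(FAMILIES))

_REVCOMP_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class PredictorNoise:
    jitter: int = 3  # max |start| offset between the two predictors' calls, bp
    undet_rate: float = 0.1  # fraction of P calls with undetermined isotype
    miss_rate: float = 0.05  # fraction of calls dropped, per predictor

    def __post_init__(self):
        if not (0 <= self.undet_rate <= 1 and 0 <= self.miss_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_pairs: int = 31  # one pair per BE-cluster-like phage/host couple
    n_satellites: int = 2  # tRNA-less phages scored against their helper
    gene_length_codons: int = 300  # typical major-capsid-protein length
    adaptation_t: float = 2.0
    pool_size_range: tuple[int, int] = (35, 45)  # helpers carry ~40 tRNA genes
    host_pool_size_range: tuple[int, int] = (60, 70)  # a complete bacterial repertoire
    gc_target: float = 0.49  # phage anticodon/sequence GC (study phages ~49%)
    host_gc_target: float = 0.71  # host GC (Streptomyces-like, ~71%)
    predictor_noise: PredictorNoise = field(default_factory=PredictorNoise)

    def __post_init__(self):
        if self.gene_length_codons < 10:
            raise ValueError("gene_length_codons must be >= 10")
        lo, hi = self.pool_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pool_size_range")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _gc_weights(strings: tuple[str, ...], gc: float | None) -> np.ndarray:
    if gc is None:
        return np.full(len(strings), 1.0 / len(strings))
    w = np.array([(gc ** sum(b in "GC" for b in s)) * ((1 - gc) ** sum(b in "AT" for b in s))
                  for s in strings])
    return w / w.sum()


def random_dna(n: int, gc: float, rng) -> str:
    rng = _rng(rng)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=probs))


#: cognate (Watson-Crick) anticodons of each synonymous family, keyed by amino acid
ANTICODONS_OF: dict[str, tuple[str, ...]] = {
    aa: tuple(_revcomp(c) for c in fam) for aa, fam in FAMILIES.items()
}


def generate_pool(
    config: SyntheticConfig,
    label: str,
    rng=None,
    gc: float | None = None,
    style: str = "covering",
) -> TgcnVector:
    """Draw a tRNA pool with total copies uniform in ``pool_size_range``.

    Two pool architectures mirror the two kinds of genome in the study
    system.  ``covering`` (phage-like): one GC-weighted isoacceptor anticodon
    per amino-acid family, remaining copies dealt round-robin so copy numbers
    stay near-uniform — the structure of a phage tRNA set serving its own
    structural genes.  ``skewed`` (host-like): anticodons drawn with
    replacement, each weighted per-base toward ``gc``, giving the
    concentrated, compositionally biased repertoire of a high-GC host.
    Anticodon GC skew follows ``gc`` (default: the config's ``gc_target``).
    """
    rng = _rng(config.seed if rng is None else rng)
    lo, hi = config.pool_size_range
    total = int(rng.integers(lo, hi + 1))
    gc = config.gc_target if gc is None else gc
    if style == "skewed":
        probs = _gc_weights(ANTICODONS, gc)
        draws = rng.choice(len(ANTICODONS), size=total, p=probs)
        return TgcnVector(dict(Counter(ANTICODONS[i] for i in draws)), origin=label)
    if style != "covering":
        raise ValueError(f"unknown pool style {style!r}")
    pool: Counter[str] = Counter()
    for aa in _AA:
        acs = ANTICODONS_OF[aa]
        pool[acs[int(rng.choice(len(acs), p=_gc_weights(acs, gc)))]] += 1
    chosen = sorted(pool)
    # trim if the requested total is below one-per-family coverage
    while sum(pool.values()) > total:
        pool.pop(chosen[int(rng.integers(len(chosen)))], None)
        chosen = sorted(pool)
    order = rng.permutation(len(chosen))
    for k in range(total - sum(pool.values())):
        pool[chosen[order[k % len(chosen)]]] += 1
    return TgcnVector(dict(pool), origin=label)


def generate_adapted_gene(
    weights: AdaptivenessWeights, length_codons: int, t: float, rng=None
) -> str:
    """CDS whose synonymous-codon choice follows P(c|aa) ∝ w_c^t.

    The amino-acid sequence is uniform over the 20 families; an ATG start and
    a TAA stop are added around ``length_codons`` body codons.  Selection is
    done in log space so large t degrades gracefully to the family argmax.
    """
    rng = _rng(rng)
    aa_idx = rng.integers(0, len(_AA), size=length_codons)
    codons = np.empty(length_codons, dtype=object)
    for k, aa in enumerate(_AA):
        positions = np.nonzero(aa_idx == k)[0]
        if positions.size == 0:
            continue
        fam = FAMILIES[aa]
        if len(fam) == 1:
            codons[positions] = fam[0]
            continue
        logits = t * np.log([weights.w[c] for c in fam])
        logits -= logits.max()
        p = np.exp(logits)
        picks = rng.choice(len(fam), size=positions.size, p=p / p.sum())
        codons[positions] = np.array(fam, dtype=object)[picks]
    return "ATG" + "".join(codons) + "TAA"


@dataclass
class PredictorViews:
    set_p: list[TrnaGene]  # structure-aware predictor (tRNAscan-SE-like)
    set_q: list[TrnaGene]  # second predictor (Aragorn-like)
    p_truth: list[int]  # truth index of each P entry
    q_truth: list[int]


def perturb_predictions(
    genes: list[TrnaGene], noise: PredictorNoise, rng=None
) -> PredictorViews:
    """Emit two predictor views of a truth gene set.

    P keeps truth coordinates; Q's start/end are shifted by a uniform offset
    in [-jitter, +jitter], so the inter-predictor start discrepancy is at most
    ``jitter`` bp.  A fraction of P calls is relabeled undetermined (isotype
    "Undet", anticodon unknown) and each view independently drops a fraction
    of calls.
    """
    rng = _rng(rng)
    set_p: list[TrnaGene] = []
    set_q: list[TrnaGene] = []
    p_truth: list[int] = []
    q_truth: list[int] = []
    for i, g in enumerate(genes):
        if rng.random() >= noise.miss_rate:
            p = replace(g, source="tRNAscan-SE")
            if rng.random() < noise.undet_rate:
                p = replace(p, isotype="Undet", anticodon=UNKNOWN)
            set_p.append(p)
            p_truth.append(i)
        if rng.random() >= noise.miss_rate:
            off = int(rng.integers(-noise.jitter, noise.jitter + 1)) if noise.jitter else 0
            off = max(off, 1 - g.start)
            set_q.append(replace(g, start=g.start + off, end=g.end + off, source="Aragorn"))
            q_truth.append(i)
    return PredictorViews(set_p, set_q, p_truth, q_truth)


def simulate_tai_pairs(
    config: SyntheticConfig,
    rng=None,
    params: WobbleParams | None = None,
    t: float | None = None,
    exchangeable: bool = False,
) -> list[tuple[float, float]]:
    """Fast path for calibration studies: per pair, draw a host pool and a
    phage pool, generate one focal gene adapted to the phage pool with
    strength t (default: the config's), and return (tai_host, tai_self)
    without assembling genome sequences.

    With ``exchangeable=True`` both pools are drawn from the phage pool
    distribution, so at t = 0 the two tAI values are exchangeable and the
    paired differences are symmetric about zero — the proper null for
    calibrating a signed-rank test's type-I error.  (The default host-style
    pools have a different architecture, so even an unadapted gene's tAI
    differs systematically between them.)"""
    from .seqio import count_codons
    from .tai import gene_tai

    rng = _rng(config.seed if rng is None else rng)
    params = params or WobbleParams()
    t = config.adaptation_t if t is None else t
    out = []
    for i in range(config.n_pairs):
        if exchangeable:
            other = generate_pool(config, f"other{i}", rng)
        else:
            other = host_pool(config, f"host{i}", rng)
        host_w = pool_weights(other, params)
        phage_w = pool_weights(generate_pool(config, f"phage{i}", rng), params)
        gene = generate_adapted_gene(phage_w, config.gene_length_codons, t, rng)
        counts = count_codons(gene, gene_id=f"gene{i}")
        out.append((gene_tai(counts, host_w).tai, gene_tai(counts, phage_w).tai))
    return out


# ---------------------------------------------------------------------------
# Whole-genome fixtures
# ---------------------------------------------------------------------------

_TRNA_LEN = 76
_SPACER = 60  # keeps neighbouring genes well outside any realistic merge window

def host_pool(config: SyntheticConfig, label: str, rng=None) -> TgcnVector:
    """A host-like pool: skewed architecture, host GC, host pool size."""
    rng = _rng(config.seed if rng is None else rng)
    host_cfg = replace(config, pool_size_range=config.host_pool_size_range)
    return generate_pool(host_cfg, label, rng, gc=config.host_gc_target, style="skewed")


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

_REVCOMP = str.maketrans("ACGT", "TGCA")


def _isotype_of(anticodon: str) -> str:
    codon = anticodon.translate(_REVCOMP)[::-1]
    return _AA3.get(_FWD.get(codon, ""), "Undet")


def build_genome(
    identifier: str,
    pool: TgcnVector,
    cds: dict[str, str],
    gc: float,
    rng=None,
) -> tuple[GenomeRecord, list[TrnaGene]]:
    """Assemble a linear genome carrying one tRNA gene per pool copy and the
    given CDSs (product -> sequence), separated by random spacers."""
    rng = _rng(rng)
    parts: list[str] = []
    features: list[FeatureRecord] = []
    trnas: list[TrnaGene] = []
    pos = 1

    def spacer():
        nonlocal pos
        s = random_dna(_SPACER, gc, rng)
        parts.append(s)
        pos += len(s)

    spacer()
    for anticodon, copies in sorted(pool.copies.items()):
        for _ in range(copies):
            body = random_dna(_TRNA_LEN, gc, rng)
            # place the anticodon at positions 33-35 of the gene, as in real tRNAs
            body = body[:32] + anticodon + body[35:]
            start, end = pos, pos + _TRNA_LEN - 1
            iso = _isotype_of(anticodon)
            features.append(
                FeatureRecord(
                    kind="tRNA", start=start, end=end, strand="+",
                    qualifiers={"product": f"tRNA-{iso} ({anticodon})",
                                "anticodon": f"(pos:{start + 32}..{start + 34},aa:{iso},seq:{anticodon.lower()})"},
                )
            )
            trnas.append(TrnaGene(identifier, start, end, "+", anticodon, iso, "annotation"))
            parts.append(body)
            pos = end + 1
            spacer()
    for product, seq in cds.items():
        start, end = pos, pos + len(seq) - 1
        features.append(
            FeatureRecord(kind="CDS", start=start, end=end, strand="+",
                          qualifiers={"product": product}))
        parts.append(seq)
        pos = end + 1
        spacer()
    return GenomeRecord(identifier, "".join(parts), features), trnas


@dataclass
class Panel:
    genomes: dict[str, GenomeRecord]
    manifest: PairManifest
    pools: dict[str, TgcnVector]
    trna_truth: dict[str, list[TrnaGene]]
    config: SyntheticConfig


def generate_panel(config: SyntheticConfig, params: WobbleParams | None = None) -> Panel:
    """Generate an n_pairs phage/host panel plus n_satellites satellite trios.

    Each ordinary phage carries its own tRNA pool and a major-capsid-protein
    gene adapted to that pool with strength ``adaptation_t``; each satellite
    carries no tRNA genes and its gene is adapted to its helper's pool (the
    helper is the matching ordinary phage).  Hosts carry GC-skewed pools.
    """
    rng = _rng(config.seed)
    params = params or WobbleParams()
    genomes: dict[str, GenomeRecord] = {}
    pools: dict[str, TgcnVector] = {}
    truth: dict[str, list[TrnaGene]] = {}
    entries: list[PairEntry] = []

    def add_genome(gid: str, pool: TgcnVector, cds: dict[str, str], gc: float):
        genome, trnas = build_genome(gid, pool, cds, gc, rng)
        genomes[gid] = genome
        pools[gid] = pool
        truth[gid] = trnas

    for i in range(config.n_pairs):
        phage_id, host_id = f"phage{i:02d}", f"host{i:02d}"
        hpool = host_pool(config, host_id, rng)
        ppool = generate_pool(config, phage_id, rng)
        mcp = generate_adapted_gene(
            pool_weights(ppool, params), config.gene_length_codons,
            config.adaptation_t, rng)
        add_genome(host_id, hpool, {}, config.host_gc_target)
        add_genome(phage_id, ppool, {"major capsid protein": mcp}, config.gc_target)
        entries.append(PairEntry(phage_id, host_id))

    for j in range(config.n_satellites):
        helper_id = f"phage{j:02d}"
        if helper_id not in pools:
            break
        sat_id = f"satellite{j:02d}"
        mcp = generate_adapted_gene(
            pool_weights(pools[helper_id], params), config.gene_length_codons,
            config.adaptation_t, rng)
        add_genome(sat_id, TgcnVector({}, origin=sat_id), {"major capsid protein": mcp},
                   config.gc_target)
        entries.append(PairEntry(sat_id, f"host{j:02d}", helper_id=helper_id))

    return Panel(genomes, PairManifest(entries), pools, truth, config)


def write_panel(panel: Panel, outdir) -> None:
    """Write GenBank fixtures, the pairing manifest, and tRNA truth tables."""
    from pathlib import Path

    from . import seqio
    from .trna import write_trna_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, genome in panel.genomes.items():
        seqio.write_genome(genome, outdir / f"{gid}.gbk")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("phage_id\thost_id\thelper_id\tgene_selector\n")
        for e in panel.manifest.entries:
            fh.write(f"{e.phage_id}\t{e.host_id}\t{e.helper_id or ''}\t{e.gene_selector}\n")
    all_genes = [g for genes in panel.trna_truth.values() for g in genes]
    write_trna_tsv(all_genes, outdir / "trna_truth.tsv")
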