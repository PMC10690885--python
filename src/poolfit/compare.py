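"""Pool-preference analysis: score a focal gene under candidate tRNA pools and
test paired preference with a Wilcoxon signed-rank procedure.

Each phage contributes one pair: the tAI of its focal gene (by default the
major capsid protein, the usual proxy for translational optimization in
phages) under the host pool, and under the phage's own pool — or, for a
satellite that carries no tRNA genes, under its helper's pool.  The paired
differences feed a signed-rank test whose null distribution is enumerated
exactly over sign assignments of the realized ranks (valid under ties) for
n <= 20, with a tie- and continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from . import seqio
from .tai import DEFAULT_EXCLUSIONS, WobbleParams, gene_tai, pool_weights
from .trna import TgcnVector, pool_from_annotation

# Above this n the tie-corrected normal approximation is used.  The exact
# null distribution is built by convolution, which is cheap far beyond the
# classical 2^n enumeration limit; 50 keeps the assignment counts exactly
# representable in float64 (2^50 < 2^53).
EXACT_LIMIT = 50


class ManifestError(ValueError):
    """A manifest entry references an unknown genome or is malformed."""


@dataclass(frozen=True)
class PairEntry:
    phage_id: str
    host_id: str
    helper_id: str | None = None
    gene_selector: str = "major capsid"


@dataclass
class PairManifest:
    entries: list[PairEntry] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path) -> "PairManifest":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ManifestError(f"{path}: empty manifest")
        header = lines[0].split("\t")
        required = ["phage_id", "host_id"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ManifestError(f"{path}: missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in header}
        entries = []
        for ln in lines[1:]:
            f = ln.split("\t")

            def get(col, default=""):
                i = idx.get(col)
                return f[i] if i is not None and i < len(f) else default

            entries.append(
                PairEntry(
                    phage_id=get("phage_id"),
                    host_id=get("host_id"),
                    helper_id=get("helper_id") or None,
                    gene_selector=get("gene_selector") or "major capsid",
                )
            )
        return cls(entries)


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # sum of ranks of positive differences (W+)
    p: float
    method: str  # "exact" | "approx" | "degenerate"
    n_effective: int


def _exact_tail_counts(double_ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all 2^n sign assignments of the realized ranks.

    Ranks are midranks, hence multiples of 1/2; doubling makes them integers
    and the distribution is built by convolution (equivalent to, and checked
    against, direct enumeration).  Index k of the result counts assignments
    with 2*W+ == k.
    """
    max_sum = int(double_ranks.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    return counts


def signed_rank_test(differences, alternative: str = "two-sided") -> SignedRankResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic reduced-sample treatment); |d| is
    ranked with midranks for ties; the statistic is the positive-rank sum W+.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise ValueError("empty difference list")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return SignedRankResult(statistic=0.0, p=1.0, method="degenerate", n_effective=0)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        double_ranks = np.rint(2 * ranks).astype(int)
        counts = _exact_tail_counts(double_ranks)
        total = counts.sum()
        obs = int(round(2 * w_plus))
        p_ge = counts[obs:].sum() / total
        p_le = counts[: obs + 1].sum() / total
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sd = np.sqrt(var)
        p_ge = float(norm.sf((w_plus - mean - 0.5) / sd))
        p_le = float(norm.cdf((w_plus - mean + 0.5) / sd))
        method = "approx"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return SignedRankResult(statistic=w_plus, p=float(min(p, 1.0)), method=method, n_effective=n)


@dataclass(frozen=True)
class PairRow:
    phage_id: str
    tai_host: float
    tai_alt: float
    alt_pool: str  # "self" | "helper"
    codons_used: int


@dataclass
class PairedComparison:
    rows: list[PairRow]
    statistic: float
    n_effective: int
    p_two_sided: float
    method: str

    @property
    def differences(self) -> list[float]:
        return [r.tai_alt - r.tai_host for r in self.rows]


def compare_pools(
    genomes: dict[str, seqio.GenomeRecord],
    manifest: PairManifest,
    params: WobbleParams | None = None,
    exclusions: frozenset[str] = DEFAULT_EXCLUSIONS,
    pools: dict[str, TgcnVector] | None = None,
) -> PairedComparison:
    """Score each manifest entry's focal gene under the host pool and the
    phage-self (or helper) pool, and test the paired differences.

    ``pools`` may pre-supply tGCN vectors keyed by genome id (e.g. built from
    reconciled predictor output); missing ids fall back to the genome's
    annotated tRNA features.
    """
    params = params or WobbleParams()
    pools = dict(pools or {})

    def pool_of(gid: str) -> TgcnVector:
        if gid not in pools:
            pools[gid] = pool_from_annotation(genomes[gid])
        return pools[gid]

    rows: list[PairRow] = []
    for entry in manifest.entries:
        for gid in (entry.phage_id, entry.host_id, entry.helper_id):
            if gid is not None and gid not in genomes:
                raise ManifestError(f"manifest references unknown genome {gid!r}")
        phage = genomes[entry.phage_id]
        cds = seqio.extract_cds(phage, entry.gene_selector)
        counts = seqio.count_codons(cds, gene_id=f"{entry.phage_id}:{entry.gene_selector}")

        host_pool = pool_of(entry.host_id)
        self_pool = pool_of(entry.phage_id)
        if self_pool.total > 0:
            alt_pool, alt_label = self_pool, "self"
        elif entry.helper_id is not None:
            alt_pool, alt_label = pool_of(entry.helper_id), "helper"
        else:
            raise ValueError(
                f"{entry.phage_id}: phage carries no tRNA genes and no helper_id is "
                "given; supply a helper pool for satellites"
            )

        tai_host = gene_tai(counts, pool_weights(host_pool, params), exclusions)
        tai_alt = gene_tai(counts, pool_weights(alt_pool, params), exclusions)
        rows.append(
            PairRow(
                phage_id=entry.phage_id,
                tai_host=tai_host.tai,
                tai_alt=tai_alt.tai,
                alt_pool=alt_label,
                codons_used=tai_host.codons_used,
            )
        )

    sr = signed_rank_test([r.tai_alt - r.tai_host for r in rows], alternative="two-sided")
    return PairedComparison(
        rows=rows,
        statistic=sr.statistic,
        n_effective=sr.n_effective,
        p_two_sided=sr.p,
        method=sr.method,
    )
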