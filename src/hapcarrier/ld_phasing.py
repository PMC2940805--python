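"""EM haplotype-frequency estimation and pairwise linkage disequilibrium.

Two estimation problems share the machinery here:

* the classic two-marker EM for the four gamete frequencies f(AB),
  f(Ab), f(aB), f(ab) from unphased dosages, from which D, D' (Lewontin's
  normalized coefficient), the LOD likelihood-ratio statistic and r^2
  are derived; and
* the multi-marker EM over the haplotype space of a block of markers,
  with a partition-ligation strategy for long blocks: estimate within
  sub-blocks of at most ``block_size`` consecutive markers, retain the
  most frequent haplotypes per sub-block, and merge adjacent blocks
  hierarchically with EM restricted to the retained combinations.

Individuals with a missing genotype at any marker of the block are
dropped (listwise deletion) before estimation. The EM log-likelihood is
non-decreasing across iterations by construction; the implementation
tracks it and exposes the trace for testing.

Alleles are coded 0 (major) / 1 (minor) internally; haplotypes are
rendered as strings using per-marker allele characters when supplied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GameteTable",
    "LDStats",
    "HaplotypeDistribution",
    "PhaseAssignment",
    "em_gamete_frequencies",
    "ld_statistics",
    "pairwise_ld",
    "em_haplotype_frequencies",
    "binomial_se",
    "assign_phases",
]


@dataclass
class GameteTable:
    """Two-locus gamete frequencies; A/B are the minor alleles.

    ``n_chromosomes`` is the chromosome count behind the estimate (0 for
    a hand-built table; then the LOD is only defined at equilibrium).
    """

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float

    n_chromosomes: int = 0

    def __post_init__(self) -> None:
        f = self.freqs
        if (f < -1e-12).any():
            raise ValueError("gamete frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"gamete frequencies sum to {f.sum()}, not 1")

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


@dataclass
class LDStats:
    """Pairwise LD summaries for one marker pair."""

    D: float
    D_prime: float
    LOD: float
    r2: float


@dataclass
class HaplotypeDistribution:
    """Estimated haplotype frequency distribution over an ordered marker set."""

    markers: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    se: np.ndarray
    n_chromosomes: int
    codes: list[tuple[int, ...]] = field(default_factory=list)
    log_likelihood: float = float("nan")
    loglik_trace: list[float] = field(default_factory=list)
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if (self.frequencies < -1e-12).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-6:
            raise ValueError("haplotype frequencies must sum to 1")
        k = len(self.markers)
        if any(len(h) != k for h in self.haplotypes):
            raise ValueError("haplotype string length must equal marker count")

    def frequency_of(self, haplotype: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0


@dataclass
class PhaseAssignment:
    individual_id: str
    hap1: str
    hap2: str
    posterior: float
    flagged: bool = False


def binomial_se(freq: float, chromosomes: int) -> float:
    """Binomial standard error of a proportion: sqrt(p(1-p)/2n)."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if chromosomes < 1:
        raise ValueError("chromosome count must be >= 1")
    return float(np.sqrt(freq * (1.0 - freq) / chromosomes))


# ---------------------------------------------------------------------------
# two-marker EM


def em_gamete_frequencies(
    dosages1: Sequence[float],
    dosages2: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> GameteTable:
    """ML gamete frequencies for two markers from unphased dosages.

    Individuals missing either marker are dropped. Only the
    double-heterozygote class is phase-ambiguous; EM iterates its
    cis/trans split until the log-likelihood changes by less than
    ``tol``.
    """
    d1 = np.asarray(dosages1, dtype=float)
    d2 = np.asarray(dosages2, dtype=float)
    ok = np.isfinite(d1) & np.isfinite(d2)
    d1, d2 = d1[ok].astype(int), d2[ok].astype(int)
    n = d1.size
    if n == 0:
        raise ValueError("no individuals with both markers genotyped")

    # 3x3 genotype table; dosage counts the minor allele
    table = np.zeros((3, 3), dtype=float)
    for g1, g2 in zip(d1, d2):
        table[g1, g2] += 1
    n_dh = table[1, 1]

    # unambiguous gamete contributions (AB, Ab, aB, ab)
    base = np.zeros(4)
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (g1, g2), gam in contrib.items():
        base += table[g1, g2] * np.asarray(gam)

    def loglik(f: np.ndarray) -> float:
        ll = 0.0
        probs = {
            (0, 0): f[3] ** 2, (0, 1): 2 * f[2] * f[3], (0, 2): f[2] ** 2,
            (1, 0): 2 * f[1] * f[3], (1, 2): 2 * f[0] * f[2],
            (2, 0): f[1] ** 2, (2, 1): 2 * f[0] * f[1], (2, 2): f[0] ** 2,
            (1, 1): 2 * f[0] * f[3] + 2 * f[1] * f[2],
        }
        for g, p in probs.items():
            c = table[g]
            if c:
                if p <= 0:
                    return -np.inf
                ll += c * np.log(p)
        return ll

    # start: split double heterozygotes evenly
    pi = 0.5
    f = (base + n_dh * np.array([pi, 1 - pi, 1 - pi, pi])) / (2 * n)
    ll_old = loglik(f)
    converged = n_dh == 0
    for _ in range(max_iter):
        if converged:
            break
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        pi = 0.5 if cis + trans == 0 else cis / (cis + trans)
        f = (base + n_dh * np.array([pi, 1 - pi, 1 - pi, pi])) / (2 * n)
        ll = loglik(f)
        if abs(ll - ll_old) < tol:
            converged = True
        ll_old = ll
    if not converged:
        warnings.warn(
            f"two-marker EM did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
        )
    f = np.clip(f, 0.0, None)
    f = f / f.sum()
    return GameteTable(*f, n_chromosomes=2 * n)


def ld_statistics(gametes: GameteTable) -> LDStats:
    """D, D', LOD and r^2 from a gamete-frequency table.

    D' and r^2 are NaN when either marker is monomorphic. The LOD is
    the base-10 log likelihood ratio of the estimated gamete
    frequencies against linkage equilibrium, evaluated on the
    multinomial expected gamete counts ``n_chromosomes * f``; with no
    chromosome count recorded it is 0 at equilibrium and NaN otherwise.
    """
    f = gametes.freqs
    pA, pB = gametes.p_A, gametes.p_B
    pa, pb = 1.0 - pA, 1.0 - pB
    D = gametes.f_AB - pA * pB

    if min(pA, pa, pB, pb) <= 0:
        d_prime = float("nan")
        r2 = float("nan")
    else:
        if D > 0:
            d_max = min(pA * pb, pa * pB)
        else:
            d_max = min(pA * pB, pa * pb)
        d_prime = 0.0 if d_max == 0 else D / d_max
        r2 = D * D / (pA * pa * pB * pb)

    eq = np.array([pA * pB, pA * pb, pa * pB, pa * pb])
    if gametes.n_chromosomes > 0:
        lod = 0.0
        for fg, eg in zip(f, eq):
            if fg > 0:
                lod += gametes.n_chromosomes * fg * np.log10(fg / eg)
    else:
        lod = 0.0 if abs(D) < 1e-12 else float("nan")
    return LDStats(D=float(D), D_prime=float(d_prime), LOD=float(lod), r2=float(r2))


def pairwise_ld(
    dosages1: Sequence[float], dosages2: Sequence[float], **em_kwargs
) -> LDStats:
    """EM gamete estimation followed by LD summaries, in one call."""
    return ld_statistics(em_gamete_frequencies(dosages1, dosages2, **em_kwargs))


# ---------------------------------------------------------------------------
# multi-marker EM with partition-ligation


def _consistent_pairs(
    genotype: tuple[int, ...]
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs summing to the genotype.

    2^(h-1) pairs for h heterozygous markers (the first het site is
    anchored to break the ordering symmetry).
    """
    het = [j for j, g in enumerate(genotype) if g == 1]
    base = [g // 2 for g in genotype]  # 0 -> 0, 2 -> 1 at homozygous sites
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = list(base)
        h2 = list(base)
        h1[het[0]] = 1
        h2[het[0]] = 0
        for j, b in zip(het[1:], bits):
            h1[j] = b
            h2[j] = 1 - b
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _em_on_pairs(
    genotype_counts: dict[tuple[int, ...], int],
    pairs_by_genotype: dict[tuple[int, ...], list[tuple[tuple[int, ...], tuple[int, ...]]]],
    tol: float,
    max_iter: int,
    restarts: int,
    rng: np.random.Generator,
) -> tuple[dict[tuple[int, ...], float], float, list[float]]:
    """EM for haplotype frequencies given consistent pairs per genotype.

    Returns the best (frequencies, log-likelihood, trace) over
    ``restarts`` starts (uniform plus Dirichlet draws).
    """
    haps = sorted({h for pairs in pairs_by_genotype.values() for p in pairs for h in p})
    index = {h: i for i, h in enumerate(haps)}
    m = len(haps)
    n_chrom = 2 * sum(genotype_counts.values())

    # genotype -> (pair index arrays, het multiplicity)
    compiled = []
    for g, count in genotype_counts.items():
        pairs = pairs_by_genotype[g]
        i1 = np.array([index[p[0]] for p in pairs])
        i2 = np.array([index[p[1]] for p in pairs])
        mult = np.array([2.0 if p[0] != p[1] else 1.0 for p in pairs])
        compiled.append((count, i1, i2, mult))

    def run(f0: np.ndarray) -> tuple[np.ndarray, float, list[float]]:
        f = f0.copy()
        trace: list[float] = []
        ll_old = -np.inf
        for _ in range(max_iter):
            counts = np.zeros(m)
            ll = 0.0
            for count, i1, i2, mult in compiled:
                w = mult * f[i1] * f[i2]
                tot = w.sum()
                if tot <= 0:
                    # genotype unreachable under current f: restart weightless
                    ll = -np.inf
                    break
                post = w / tot
                np.add.at(counts, i1, count * post)
                np.add.at(counts, i2, count * post)
                ll += count * np.log(tot)
            if not np.isfinite(ll):
                break
            trace.append(ll)
            f = counts / n_chrom
            if ll - ll_old < tol and np.isfinite(ll_old):
                break
            ll_old = ll
        return f, (trace[-1] if trace else -np.inf), trace

    starts = [np.full(m, 1.0 / m)]
    for _ in range(max(0, restarts - 1)):
        starts.append(rng.dirichlet(np.ones(m)))
    best = None
    for f0 in starts:
        f, ll, trace = run(f0)
        if best is None or ll > best[1]:
            best = (f, ll, trace)
    f, ll, trace = best
    return {h: float(f[index[h]]) for h in haps}, ll, trace


def _distinct_genotypes(geno: np.ndarray) -> dict[tuple[int, ...], int]:
    counts: dict[tuple[int, ...], int] = {}
    for row in geno:
        g = tuple(int(x) for x in row)
        counts[g] = counts.get(g, 0) + 1
    return counts


def em_haplotype_frequencies(
    genotypes: np.ndarray,
    markers: Optional[Sequence[str]] = None,
    subset: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    prune_floor: float = 1e-3,
    block_size: int = 8,
    top_k: int = 20,
    full_em_limit: int = 10,
    alleles: Optional[Sequence[tuple[str, str]]] = None,
) -> HaplotypeDistribution:
    """Estimate haplotype frequencies over ``k`` ordered markers by EM.

    ``genotypes`` is an (n, k) dosage matrix (0/1/2, NaN missing);
    ``subset`` optionally masks rows (e.g. carriers only). Rows with a
    missing value at any marker are dropped. For ``k <= full_em_limit``
    the EM runs over the full space of haplotypes consistent with the
    observed genotypes; longer marker sets use partition-ligation with
    consecutive blocks of at most ``block_size`` markers, retaining the
    ``top_k`` most frequent haplotypes per block. Estimates below
    ``prune_floor`` are pruned and the remainder renormalized.
    """
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x markers) array")
    n, k = geno.shape
    if k < 1:
        raise ValueError("need at least one marker")
    if markers is None:
        markers = [f"M{j + 1}" for j in range(k)]
    markers = list(markers)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if not subset.any():
            raise ValueError("subset selects no individuals")
        geno = geno[subset]
    for j in range(k):
        if not np.isfinite(geno[:, j]).any():
            raise ValueError(f"marker {markers[j]!r} is missing in every "
                             "selected individual")
    complete = np.isfinite(geno).all(axis=1)
    geno = geno[complete]
    if geno.shape[0] == 0:
        raise ValueError("no individuals with complete genotypes in the block")
    rng = np.random.default_rng(seed)
    n_chrom = 2 * geno.shape[0]

    if k <= full_em_limit:
        gcounts = _distinct_genotypes(geno)
        pairs = {g: _consistent_pairs(g) for g in gcounts}
        freqs, ll, trace = _em_on_pairs(gcounts, pairs, tol, max_iter, restarts, rng)
    else:
        freqs, ll, trace = _partition_ligation(
            geno, tol, max_iter, restarts, rng, block_size, top_k
        )

    # prune and renormalize
    kept = {h: f for h, f in freqs.items() if f >= prune_floor}
    if not kept:  # keep the single best rather than return nothing
        best = max(freqs, key=freqs.get)
        kept = {best: freqs[best]}
    total = sum(kept.values())
    codes = sorted(kept, key=lambda h: (-kept[h], h))
    fr = np.array([kept[h] / total for h in codes])

    if alleles is None:
        alleles = [("1", "0")] * k
    alleles = list(alleles)
    hap_strings = [
        "".join(alleles[j][0] if h[j] == 1 else alleles[j][1] for j in range(k))
        for h in codes
    ]
    se = np.array([binomial_se(f, n_chrom) for f in fr])
    return HaplotypeDistribution(
        markers=markers,
        haplotypes=hap_strings,
        frequencies=fr,
        se=se,
        n_chromosomes=n_chrom,
        codes=[tuple(h) for h in codes],
        log_likelihood=ll,
        loglik_trace=trace,
        alleles=alleles,
    )


def _partition_ligation(
    geno: np.ndarray,
    tol: float,
    max_iter: int,
    restarts: int,
    rng: np.random.Generator,
    block_size: int,
    top_k: int,
) -> tuple[dict[tuple[int, ...], float], float, list[float]]:
    """Blockwise EM then hierarchical ligation of adjacent blocks."""
    k = geno.shape[1]
    n_blocks = int(np.ceil(k / block_size))
    bounds = [
        (b * k // n_blocks, (b + 1) * k // n_blocks) for b in range(n_blocks)
    ]

    def block_em(lo: int, hi: int) -> list[tuple[int, ...]]:
        sub = geno[:, lo:hi]
        gcounts = _distinct_genotypes(sub)
        pairs = {g: _consistent_pairs(g) for g in gcounts}
        freqs, _, _ = _em_on_pairs(gcounts, pairs, tol, max_iter, restarts, rng)
        ranked = sorted(freqs, key=lambda h: -freqs[h])
        return ranked[:top_k]

    segments = [(lo, hi, block_em(lo, hi)) for lo, hi in bounds]

    def ligate(left, right):
        lo, mid_l, lh = left
        mid_r, hi, rh = right
        assert mid_l == mid_r
        candidates = {l + r for l in lh for r in rh}
        gcounts = _distinct_genotypes(geno[:, lo:hi])
        pairs_by_g: dict = {}
        dropped = 0
        for g in list(gcounts):
            pairs = []
            for h1 in candidates:
                if any(gj != 1 and h1j != gj // 2 for gj, h1j in zip(g, h1)):
                    continue
                h2 = tuple(gj - h1j for gj, h1j in zip(g, h1))
                if h2 in candidates and h2 >= h1:
                    pairs.append((h1, h2))
            if pairs:
                pairs_by_g[g] = pairs
            else:
                dropped += gcounts.pop(g)
        if dropped:
            warnings.warn(
                f"{dropped} individuals dropped during ligation: genotype "
                "inconsistent with retained block haplotypes",
                RuntimeWarning,
            )
        freqs, ll, trace = _em_on_pairs(
            gcounts, pairs_by_g, tol, max_iter, restarts, rng
        )
        ranked = sorted(freqs, key=lambda h: -freqs[h])
        return (lo, hi, ranked[:top_k]), (freqs, ll, trace)

    result = None
    while len(segments) > 1:
        merged = []
        i = 0
        while i < len(segments):
            if i + 1 < len(segments):
                seg, result = ligate(segments[i], segments[i + 1])
                merged.append(seg)
                i += 2
            else:
                merged.append(segments[i])
                i += 1
        segments = merged
    assert result is not None  # k > block_size guarantees >= 2 initial blocks
    return result


# ---------------------------------------------------------------------------
# phase assignment


def assign_phases(
    genotypes: np.ndarray,
    distribution: HaplotypeDistribution,
    individual_ids: Optional[Sequence[str]] = None,
) -> list[PhaseAssignment]:
    """Most-likely haplotype pair per individual under the distribution.

    Among pairs (h1, h2) of retained haplotypes consistent with the
    genotype, the pair maximizing f(h1) f(h2) (x2 when h1 != h2) is
    returned with its normalized posterior. Missing markers are treated
    as unconstrained. Individuals whose genotype is consistent with no
    retained pair get a uniform fallback over raw consistent pairs
    (missing filled with the major allele), flagged.
    """
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim == 1:
        geno = geno[None, :]
    n, k = geno.shape
    if k != len(distribution.markers):
        raise ValueError("genotype width does not match distribution markers")
    if individual_ids is None:
        individual_ids = [str(i) for i in range(n)]
    hap_codes = distribution.codes
    hap_freq = {h: f for h, f in zip(hap_codes, distribution.frequencies)}
    hap_str = {h: s for h, s in zip(hap_codes, distribution.haplotypes)}
    alleles = distribution.alleles or [("1", "0")] * k

    def code_to_str(h: tuple[int, ...]) -> str:
        return "".join(alleles[j][0] if h[j] == 1 else alleles[j][1] for j in range(k))

    out: list[PhaseAssignment] = []
    for i in range(n):
        g = geno[i]
        pairs: list[tuple[tuple, tuple, float]] = []
        for h1 in hap_codes:
            ok = True
            for j in range(k):
                if np.isfinite(g[j]) and g[j] != 1 and h1[j] != int(g[j]) // 2:
                    ok = False
                    break
            if not ok:
                continue
            for h2 in hap_codes:
                if h2 < h1:
                    continue
                match = True
                for j in range(k):
                    if np.isfinite(g[j]) and h1[j] + h2[j] != int(g[j]):
                        match = False
                        break
                if match:
                    w = hap_freq[h1] * hap_freq[h2] * (2.0 if h1 != h2 else 1.0)
                    pairs.append((h1, h2, w))
        if pairs and sum(w for *_, w in pairs) > 0:
            total = sum(w for *_, w in pairs)
            h1, h2, w = max(pairs, key=lambda t: t[2])
            out.append(
                PhaseAssignment(
                    individual_id=str(individual_ids[i]),
                    hap1=hap_str[h1],
                    hap2=hap_str[h2],
                    posterior=w / total,
                    flagged=False,
                )
            )
        else:
            # uniform fallback over raw consistent pairs
            filled = tuple(0 if not np.isfinite(x) else int(x) for x in g)
            raw = _consistent_pairs(filled)
            h1, h2 = raw[0]
            out.append(
                PhaseAssignment(
                    individual_id=str(individual_ids[i]),
                    hap1=code_to_str(h1),
                    hap2=code_to_str(h2),
                    posterior=1.0 / len(raw),
                    flagged=True,
                )
            )
    return out


def expected_haplotype_counts(
    genotypes: np.ndarray, distribution: HaplotypeDistribution
) -> np.ndarray:
    """Per-individual EM-posterior expected count of each retained haplotype.

    Returns an (n, H) matrix; each row sums to 2 for individuals whose
    genotype is consistent with at least one retained pair (rows with no
    consistent pair are all-zero). These fractional counts are the
    per-individual contributions entering haplotype association tests.
    """
    geno = np.asarray(genotypes, dtype=float)
    n, k = geno.shape
    hap_codes = distribution.codes
    H = len(hap_codes)
    idx = {h: a for a, h in enumerate(hap_codes)}
    freq = distribution.frequencies
    out = np.zeros((n, H))
    cache: dict[tuple, np.ndarray] = {}
    for i in range(n):
        g = tuple(-1 if not np.isfinite(x) else int(x) for x in geno[i])
        if g in cache:
            out[i] = cache[g]
            continue
        row = np.zeros(H)
        weights = []
        for h1 in hap_codes:
            ok = all(gj in (-1, 1) or h1[j] == gj // 2 for j, gj in enumerate(g))
            if not ok:
                continue
            for h2 in hap_codes:
                if h2 < h1:
                    continue
                if all(gj == -1 or h1[j] + h2[j] == gj for j, gj in enumerate(g)):
                    w = freq[idx[h1]] * freq[idx[h2]] * (2.0 if h1 != h2 else 1.0)
                    weights.append((idx[h1], idx[h2], w))
        total = sum(w for *_, w in weights)
        if total > 0:
            for a, b, w in weights:
                row[a] += w / total
                row[b] += w / total
        cache[g] = row
        out[i] = row
    return out
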