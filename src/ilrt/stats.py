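"""Statistical tests of the reverse-transcriptase model of intron loss.

Kernels (Fisher, chi-square, Mann-Whitney, Spearman) follow the printed
analysis conventions: Fisher's two-sided p defaults to tail doubling (the
minimum-likelihood convention is available), the chi-square uses Yates'
continuity correction, and the Mann-Whitney test is exact for small
tie-free samples.  The combinatorial null for simultaneous adjacent intron
loss — the probability distribution of the number of clusters when each of
k lost introns out of n is lost independently — and its cross-gene
convolution are implemented from first principles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import comb

logger = logging.getLogger(__name__)


def _check_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    a, b, c, d = (int(x) for x in arr.ravel())
    return a, b, c, d


def fisher_exact_2x2(table, convention: str = "doubling") -> float:
    """Two-sided Fisher's exact test on a 2x2 table.

    ``doubling`` doubles the smaller hypergeometric tail (capped at 1);
    ``min-likelihood`` sums all tables with likelihood at most that of the
    observed one.
    """
    a, b, c, d = _check_table(table)
    if convention == "min-likelihood":
        return float(sps.fisher_exact([[a, b], [c, d]])[1])
    if convention != "doubling":
        raise ValueError(f"unknown convention {convention!r}")
    hg = sps.hypergeom(a + b + c + d, a + b, a + c)
    lower = hg.cdf(a)
    upper = hg.sf(a - 1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def chi_square_2x2(table, correction: bool = True) -> float:
    """Pearson chi-square (1 df) on a 2x2 table, Yates-corrected by default."""
    a, b, c, d = _check_table(table)
    arr = np.array([[a, b], [c, d]])
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    return float(sps.chi2_contingency(arr, correction=correction)[1])


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both samples are small (min(n, m) <= 8) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("empty sample")
    tie_free = len(set(x) | set(y)) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and tie_free) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p by t approximation."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# adjacency null (independent-loss cluster distribution)


def cluster_distribution(n: int, k: int) -> dict[int, float]:
    """P(c clusters) when k of n introns are lost independently.

    Losing k introns uniformly at random among the C(n, k) subsets, the
    lost introns form c maximal runs ("clusters") with probability

        P(c) = C(k-1, c-1) * C(n-k+1, c) / C(n, k),

    the classical runs distribution; the adjacent-pair count is a = k - c.
    """
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    total = comb(n, k, exact=True)
    out: dict[int, float] = {}
    c_hi = min(k, n - k + 1)
    for c in range(1, c_hi + 1):
        out[c] = comb(k - 1, c - 1, exact=True) * comb(n - k + 1, c, exact=True) / total
    return out


@dataclass
class AdjacencyNull:
    """Cross-gene null for total adjacent pairs and total clusters."""

    genes: list[tuple[int, int]]  # (n introns, k losses) per gene
    pair_pmf: np.ndarray  # P(total adjacent pairs = a), index a
    cluster_pmf: np.ndarray  # P(total clusters = c), index c
    observed_pairs: int | None = None
    observed_clusters: int | None = None
    p_pairs: float | None = None  # P(total pairs >= observed)
    p_clusters: float | None = None  # P(total clusters <= observed)


def adjacency_pvalue(
    genes: list[tuple[int, int]],
    observed_pairs: int | None = None,
    observed_clusters: int | None = None,
) -> AdjacencyNull:
    """Convolve per-gene cluster-count nulls across genes.

    Returns tail probabilities P(total adjacent pairs >= observed) and
    P(total clusters <= observed) under independent loss of each intron
    within each gene.
    """
    if not genes:
        raise ValueError("no genes supplied")
    pair_pmf = np.array([1.0])
    cluster_pmf = np.array([1.0])
    for n, k in genes:
        dist = cluster_distribution(n, k)
        c_max = max(dist)
        pmf_c = np.zeros(c_max + 1)
        pmf_a = np.zeros(k - min(dist) + 1)
        for c, p in dist.items():
            pmf_c[c] += p
            pmf_a[k - c] += p
        pair_pmf = np.convolve(pair_pmf, pmf_a)
        cluster_pmf = np.convolve(cluster_pmf, pmf_c)
    null = AdjacencyNull(genes=list(genes), pair_pmf=pair_pmf,
                         cluster_pmf=cluster_pmf,
                         observed_pairs=observed_pairs,
                         observed_clusters=observed_clusters)
    if observed_pairs is not None:
        null.p_pairs = (
            float(pair_pmf[observed_pairs:].sum()) if observed_pairs < len(pair_pmf) else 0.0
        )
    if observed_clusters is not None:
        null.p_clusters = float(cluster_pmf[: observed_clusters + 1].sum())
    return null


# ---------------------------------------------------------------------------
# micro-homology (direct repeats around splice sites)


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact substring shared by two sequences."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def microhomology_scan(
    upstream_exon: str,
    intron: str,
    downstream_exon: str,
    min_len: int = 6,
    window: int = 15,
) -> tuple[bool, int]:
    """Direct-repeat search around the two splice sites of one intron.

    Takes ``window`` nt on each side of the 5' splice site and of the 3'
    splice site; a direct repeat is an identical substring of length >=
    ``min_len`` occurring in both windows.  Shorter available sequence is
    used as is.  Returns ``(found, longest shared length)``.
    """
    w5 = upstream_exon[-window:] + intron[:window]
    w3 = intron[-window:] + downstream_exon[:window]
    length = longest_common_substring(w5, w3)
    return length >= min_len, length


# ---------------------------------------------------------------------------
# positional bias


@dataclass(frozen=True)
class SitePosition:
    """mRNA-coordinate record for one intron position."""

    gene_id: str
    cds_offset: int
    mrna_length: int
    is_last: bool  # 3'-most intron of its gene

    @property
    def relative_position(self) -> float:
        if self.mrna_length <= 0:
            raise ValueError("mRNA length must be positive")
        return self.cds_offset / self.mrna_length

    @property
    def distance_to_3p(self) -> int:
        return self.mrna_length - self.cds_offset


def positional_bias(lost: list[SitePosition], conserved: list[SitePosition]) -> dict:
    """Compare lost vs conserved intron positions along the mRNA.

    Relative position is the distance to the 5' end divided by the mRNA
    length; the absolute distance to the 3' end is compared as well.  Also
    counts lost introns that are 3'-most and that lie in the 3' half.
    """
    if not lost or not conserved:
        raise ValueError("both site groups must be non-empty")
    rel_l = [s.relative_position for s in lost]
    rel_c = [s.relative_position for s in conserved]
    d3_l = [s.distance_to_3p for s in lost]
    d3_c = [s.distance_to_3p for s in conserved]
    return {
        "n_lost": len(lost),
        "n_conserved": len(conserved),
        "mean_relative_lost": float(np.mean(rel_l)),
        "mean_relative_conserved": float(np.mean(rel_c)),
        "relative_position_mwu_p": mann_whitney_u(rel_l, rel_c),
        "mean_dist3_lost": float(np.mean(d3_l)),
        "mean_dist3_conserved": float(np.mean(d3_c)),
        "dist3_mwu_p": mann_whitney_u(d3_l, d3_c),
        "n_lost_3prime_most": sum(s.is_last for s in lost),
        "n_lost_3prime_half": sum(r > 0.5 for r in rel_l),
    }


# ---------------------------------------------------------------------------
# housekeeping and association suite


def housekeeping_classify(
    expression,
    cutoff: float = 200.0,
    excluded_tissues: tuple[str, ...] = ("testis", "ovary"),
) -> dict[str, bool]:
    """Housekeeping = expressed (> cutoff, strict) in every surveyed tissue.

    Reproductive organs are dropped beforehand (germline/somatic mixtures);
    genes with missing values are excluded and logged.
    """
    if expression.shape[1] == 0:
        raise ValueError("expression matrix has no tissues")
    cols = [c for c in expression.columns if c not in excluded_tissues]
    sub = expression[cols]
    out: dict[str, bool] = {}
    for gene, row in sub.iterrows():
        if row.isna().any() or len(row) == 0:
            logger.info("gene %s excluded from housekeeping call (missing data)", gene)
            continue
        out[gene] = bool((row > cutoff).all())
    return out


def association_suite(
    il_genes: set[str],
    nil_genes: set[str],
    pp_counts: dict[str, int],
    annotations,
    expression,
    mrna_lengths: dict[str, int],
    intron_counts: dict[str, int],
    losses_per_gene: dict[str, int],
    expression_cutoff: float = 200.0,
    excluded_tissues: tuple[str, ...] = ("testis", "ovary"),
    fisher_convention: str = "doubling",
) -> dict:
    """Every group-comparison statistic of the processed-pseudogene study.

    IL genes carry >= 1 called intron loss; NIL genes have exclusively
    conserved introns.  Emits raw counts alongside each statistic so any
    multiple-testing correction can be applied downstream.
    """
    if not il_genes or not nil_genes:
        raise ValueError("IL and NIL sets must both be non-empty")
    if il_genes & nil_genes:
        raise ValueError("IL and NIL sets overlap")

    def pp(g: str) -> int:
        return int(pp_counts.get(g, 0))

    il, nil = sorted(il_genes), sorted(nil_genes)
    report: dict = {}

    # (i) parental-of-PP enrichment in IL genes
    a = sum(pp(g) > 0 for g in il)
    c = sum(pp(g) > 0 for g in nil)
    table = [[a, len(il) - a], [c, len(nil) - c]]
    report["parental_pp"] = {
        "table": table,
        "pct_il_parental": 100.0 * a / len(il),
        "pct_nil_parental": 100.0 * c / len(nil),
        "fisher_p": fisher_exact_2x2(table, fisher_convention),
    }

    # (ii) PP abundance per gene
    il_pp = [pp(g) for g in il]
    nil_pp = [pp(g) for g in nil]
    report["pp_per_gene"] = {
        "mean_il": float(np.mean(il_pp)),
        "mean_nil": float(np.mean(nil_pp)),
        "mwu_p": mann_whitney_u(il_pp, nil_pp),
    }

    # (iii) intron-loss rate of parental vs non-parental genes
    universe = il + nil
    parental = [g for g in universe if pp(g) > 0]
    nonparental = [g for g in universe if pp(g) == 0]
    if parental and nonparental:
        lp = [losses_per_gene.get(g, 0) for g in parental]
        ln = [losses_per_gene.get(g, 0) for g in nonparental]
        report["loss_rate"] = {
            "mean_parental": float(np.mean(lp)),
            "mean_nonparental": float(np.mean(ln)),
            "mwu_p": mann_whitney_u(lp, ln),
        }

    # (iv) soluble-protein proxies (absence of SP / TM domain)
    ann = annotations.set_index("gene_id") if "gene_id" in annotations.columns else annotations
    for key, col in (("signal_peptide_absence", "has_signal_peptide"),
                     ("tm_absence", "has_tm_domain")):
        il_ann = [g for g in il if g in ann.index]
        nil_ann = [g for g in nil if g in ann.index]
        if not il_ann or not nil_ann:
            continue
        a = sum(not ann.loc[g, col] for g in il_ann)
        c = sum(not ann.loc[g, col] for g in nil_ann)
        table = [[a, len(il_ann) - a], [c, len(nil_ann) - c]]
        try:
            p = chi_square_2x2(table)
        except ValueError:  # degenerate margin: no trait variation at all
            p = 1.0
        report[key] = {
            "table": table,
            "pct_il_absent": 100.0 * a / len(il_ann),
            "pct_nil_absent": 100.0 * c / len(nil_ann),
            "chi2_p": p,
        }

    # (v) housekeeping enrichment
    hk = housekeeping_classify(expression, expression_cutoff, excluded_tissues)
    il_hk = [g for g in il if g in hk]
    nil_hk = [g for g in nil if g in hk]
    if il_hk and nil_hk:
        a = sum(hk[g] for g in il_hk)
        c = sum(hk[g] for g in nil_hk)
        table = [[a, len(il_hk) - a], [c, len(nil_hk) - c]]
        report["housekeeping"] = {
            "table": table,
            "n_il": len(il_hk),
            "n_nil": len(nil_hk),
            "pct_il_housekeeping": 100.0 * a / len(il_hk),
            "pct_nil_housekeeping": 100.0 * c / len(nil_hk),
            "fisher_p": fisher_exact_2x2(table, fisher_convention),
        }

    # (vi) mRNA-length confounder and intron-count vs PP-count correlation
    def lengths(genes):
        return [mrna_lengths[g] for g in genes if g in mrna_lengths]

    il_len, nil_len = lengths(il), lengths(nil)
    par_len, non_len = lengths(parental), lengths(nonparental)
    report["mrna_length"] = {
        "median_il": float(np.median(il_len)) if il_len else None,
        "median_nil": float(np.median(nil_len)) if nil_len else None,
        "mwu_p_il_nil": mann_whitney_u(il_len, nil_len) if il_len and nil_len else None,
        "median_parental": float(np.median(par_len)) if par_len else None,
        "median_nonparental": float(np.median(non_len)) if non_len else None,
        "mwu_p_parental": mann_whitney_u(par_len, non_len) if par_len and non_len else None,
    }
    common = [g for g in universe if g in intron_counts]
    if len(common) >= 3:
        ic = [intron_counts[g] for g in common]
        pc = [pp(g) for g in common]
        try:
            rho, p = spearman_rho(ic, pc)
            report["intron_count_vs_pp"] = {"rho": rho, "p": p, "n": len(common)}
        except ValueError:
            pass
    return report
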