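"""Per-locus diversity statistics, HWE and linkage tests, FDR correction.

All statistics are meant to run on data already collapsed to one
representative per multilocus lineage (see :mod:`msatpop.clonality`).
Expected heterozygosity is the uncorrected ``1 - sum(p**2)`` and the
deviation index is ``(H_E - H_O) / H_E``, matching the conventions the
per-locus summary tables are checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genotype import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def _genotype_pairs(matrix: GenotypeMatrix, locus_id: str, group: str | None):
    for s in matrix.samples:
        if group is not None and s.mito_type != group:
            continue
        g = s.genotypes[locus_id]
        if g[0] != MISSING:
            yield g


def allele_freqs(
    matrix: GenotypeMatrix, locus_id: str, group: str | None = None
) -> dict[int, float]:
    """Allele relative frequencies at one locus; missing calls excluded."""
    counts: dict[int, int] = {}
    total = 0
    for a, b in _genotype_pairs(matrix, locus_id, group):
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        total += 2
    if total == 0:
        raise ValueError(
            f"locus {locus_id!r} has no typed genotypes in group {group!r}"
        )
    return {allele: c / total for allele, c in sorted(counts.items())}


def expected_het(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Gene diversity ``1 - sum(p**2)`` (uncorrected)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs)
    return float(1.0 - np.sum(p * p))


def observed_het(matrix: GenotypeMatrix, locus_id: str, group: str | None = None) -> float:
    pairs = list(_genotype_pairs(matrix, locus_id, group))
    if not pairs:
        raise ValueError(f"locus {locus_id!r} untyped in group {group!r}")
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def f_is(h_e: float, h_o: float) -> float:
    """Deviation index (H_E - H_O) / H_E; undefined for monomorphic loci."""
    if h_e <= 0:
        raise ValueError("F_IS is undefined when H_E = 0")
    return (h_e - h_o) / h_e


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    group: str | None
    n: int  # typed lineages
    n_a: int
    h_e: float
    h_o: float
    f_is: float | None  # None when H_E = 0

    def __post_init__(self):
        if not 0 <= self.h_e < 1:
            raise ValueError("H_E out of [0, 1)")
        if not 0 <= self.h_o <= 1:
            raise ValueError("H_O out of [0, 1]")


def summarize_locus(
    matrix: GenotypeMatrix, locus_id: str, group: str | None = None
) -> LocusStats:
    freqs = allele_freqs(matrix, locus_id, group)
    h_e = expected_het(freqs)
    h_o = observed_het(matrix, locus_id, group)
    n = sum(1 for _ in _genotype_pairs(matrix, locus_id, group))
    return LocusStats(
        locus_id=locus_id,
        group=group,
        n=n,
        n_a=len(freqs),
        h_e=h_e,
        h_o=h_o,
        f_is=f_is(h_e, h_o) if h_e > 0 else None,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HWEResult:
    locus_id: str
    group: str | None
    statistic: float
    df: int
    p_value: float
    n: int
    low_expected: bool  # some expected genotype count < 5


def hwe_test(
    matrix: GenotypeMatrix, locus_id: str, group: str | None = None
) -> HWEResult:
    """Chi-square goodness of fit of genotype counts to HWE proportions.

    Cells are all k(k+1)/2 unordered genotypes; df = k(k-1)/2. A
    ``low_expected`` flag marks results where some expected count is
    below 5 (the chi-square approximation is then shaky).
    """
    pairs = list(_genotype_pairs(matrix, locus_id, group))
    n = len(pairs)
    freqs = allele_freqs(matrix, locus_id, group)
    alleles = list(freqs)
    k = len(alleles)
    if k < 2:
        raise ValueError(f"locus {locus_id!r} monomorphic; HWE test undefined")
    if n < 5:
        raise ValueError("need at least 5 typed lineages for the HWE test")

    obs: dict[tuple[int, int], int] = {}
    for g in pairs:
        obs[g] = obs.get(g, 0) + 1

    chi2 = 0.0
    low = False
    for i, ai in enumerate(alleles):
        for aj in alleles[i:]:
            pi, pj = freqs[ai], freqs[aj]
            e = n * (pi * pi if ai == aj else 2 * pi * pj)
            o = obs.get((ai, aj), 0)
            if e < 5:
                low = True
            if e > 0:
                chi2 += (o - e) ** 2 / e
    df = k * (k - 1) // 2
    p = float(sps.chi2.sf(chi2, df))
    return HWEResult(
        locus_id=locus_id,
        group=group,
        statistic=float(chi2),
        df=df,
        p_value=p,
        n=n,
        low_expected=low,
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    locus_a: str
    locus_b: str
    group: str | None
    g_statistic: float
    p_value: float
    n: int
    n_perm: int
    significant_after_fdr: bool | None = None


def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, ka: int, kb: int) -> float:
    """Log-likelihood-ratio G on the two-locus genotype contingency table."""
    n = codes_a.size
    table = np.bincount(codes_a * kb + codes_b, minlength=ka * kb).reshape(ka, kb)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_test(
    matrix: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    group: str | None = None,
    n_perm: int = 1000,
    seed=None,
) -> LDResult:
    """Permutation G-test of genotypic association between two loci.

    One locus's genotypes are permuted across lineages; the p-value is
    ``(1 + #{G_perm >= G_obs}) / (n_perm + 1)``.
    """
    ga, gb = [], []
    for s in matrix.samples:
        if group is not None and s.mito_type != group:
            continue
        x, y = s.genotypes[locus_a], s.genotypes[locus_b]
        if x[0] != MISSING and y[0] != MISSING:
            ga.append(x)
            gb.append(y)
    n = len(ga)
    if n < 5:
        raise ValueError(
            f"loci {locus_a!r}/{locus_b!r} share only {n} typed lineages (need >= 5)"
        )
    cat_a = {g: i for i, g in enumerate(sorted(set(ga)))}
    cat_b = {g: i for i, g in enumerate(sorted(set(gb)))}
    codes_a = np.array([cat_a[g] for g in ga])
    codes_b = np.array([cat_b[g] for g in gb])
    ka, kb = len(cat_a), len(cat_b)

    g_obs = _g_statistic(codes_a, codes_b, ka, kb)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes_b)
        if _g_statistic(codes_a, perm, ka, kb) >= g_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return LDResult(
        locus_a=locus_a,
        locus_b=locus_b,
        group=group,
        g_statistic=g_obs,
        p_value=p,
        n=n,
        n_perm=n_perm,
    )


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = q * (np.arange(1, m + 1) / m)
    passing = np.where(ranked <= thresholds)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        cutoff = ranked[passing[-1]]
        flags = p <= cutoff
    return flags


# ---------------------------------------------------------------------------
# cross-group allele sharing
# ---------------------------------------------------------------------------

def shared_allele_count(
    matrix: GenotypeMatrix,
    type_a: str,
    type_b: str,
    loci: Sequence[str] | None = None,
) -> tuple[int, int]:
    """(n_shared, n_total) distinct alleles across loci for two groups."""
    loci = list(loci) if loci is not None else matrix.locus_ids
    n_shared = 0
    n_total = 0
    for lid in loci:
        sets = []
        for grp in (type_a, type_b):
            alleles = set()
            for a, b in _genotype_pairs(matrix, lid, grp):
                alleles.update((a, b))
            sets.append(alleles)
        n_shared += len(sets[0] & sets[1])
        n_total += len(sets[0] | sets[1])
    return n_shared, n_total


# ---------------------------------------------------------------------------
# table output
# ---------------------------------------------------------------------------

def write_locus_stats_tsv(
    rows: Iterable[tuple[LocusStats, HWEResult | None]], path
) -> None:
    """TSV mirroring the characterization-table column order."""
    lines = ["locus\tgroup\tn\tN_A\tH_E\tH_O\tF_IS\tHWE_p\tHWE_low_expected"]
    for st, hwe in rows:
        fis = f"{st.f_is:.3f}" if st.f_is is not None else "NA"
        hp = f"{hwe.p_value:.4g}" if hwe is not None else "NA"
        hl = str(int(hwe.low_expected)) if hwe is not None else "NA"
        lines.append(
            f"{st.locus_id}\t{st.group or ''}\t{st.n}\t{st.n_a}\t"
            f"{st.h_e:.3f}\t{st.h_o:.3f}\t{fis}\t{hp}\t{hl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ld_tsv(results: Sequence[LDResult], path) -> None:
    lines = ["locus_a\tlocus_b\tgroup\tG\tp\tn\tn_perm\tsignificant_after_fdr"]
    for r in results:
        sig = "NA" if r.significant_after_fdr is None else str(int(r.significant_after_fdr))
        lines.append(
            f"{r.locus_a}\t{r.locus_b}\t{r.group or ''}\t{r.g_statistic:.4f}\t"
            f"{r.p_value:.6g}\t{r.n}\t{r.n_perm}\t{sig}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
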