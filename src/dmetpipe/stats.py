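"""Per-probe Fisher-exact association screening and Hardy-Weinberg testing.

Each probe contributes one 2x2 test per observed genotype category: rows are
presence/absence of that genotype, columns are the two phenotype classes
(e.g. RESP / NoRESP); NoCall samples are excluded probe by probe.  The
two-sided Fisher p-value is the sum of hypergeometric probabilities of all
tables with the observed margins whose point probability does not exceed
that of the observed table (relative tie tolerance 1e-7).  Multiple-testing
correction (Bonferroni or Benjamini-Hochberg FDR) is applied over the full
family of (probe, genotype) tests — a choice recorded in the output
metadata, since correcting over probes alone is the other defensible family.

Hardy-Weinberg equilibrium is checked per biallelic probe with the 1-df
chi-square goodness of fit of observed genotype counts against n*(p^2, 2pq,
q^2), allele frequencies estimated from the called genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_dmet import NOCALL, GenotypeTable, PhenotypeAssignment

CORRECTORS = ("none", "bonferroni", "fdr_bh")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d): genotype present/absent x class A/class B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class HWEResult:
    probe_id: str
    allele_counts: dict[str, int]
    genotype_counts: tuple[int, int, int]  # hom-major, het, hom-minor
    chi_square: float
    p_value: float
    applicable: bool


def build_contingency(
    probe_row: pd.Series,
    assignment: PhenotypeAssignment,
    genotype_category: str,
) -> ContingencyTable2x2:
    """2x2 presence/absence table for one genotype at one probe.

    a = class-A samples carrying the genotype, b = class-A samples with any
    other called genotype; c, d likewise for class B.  NoCall samples and
    unassigned samples are excluded.
    """
    label_a, label_b = assignment.class_labels
    called = probe_row[probe_row != NOCALL]
    if genotype_category not in set(called.values):
        raise ValueError(
            f"genotype {genotype_category!r} not observed at this probe"
        )
    a = b = c = d = 0
    for sample, call in called.items():
        label = assignment.assignment.get(sample)
        if label == label_a:
            if call == genotype_category:
                a += 1
            else:
                b += 1
        elif label == label_b:
            if call == genotype_category:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


@lru_cache(maxsize=1_000_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(
        sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule).

    Memoized on the cell counts: screening runs re-test many identical
    tables.
    """
    return _fisher_p(t.a, t.b, t.c, t.d)


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Cross-product ratio ad/bc; zero cells follow the inf/0 convention."""
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def correct_pvalues(p_values, method: str = "bonferroni") -> np.ndarray:
    """Adjust a list of p-values; output order matches input order."""
    if method not in CORRECTORS:
        raise ValueError(f"method must be one of {CORRECTORS}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    return multipletests(p, method=method)[1]


def hwe_test(probe_row: pd.Series, probe_id: str = "") -> HWEResult:
    """Hardy-Weinberg 1-df chi-square for one probe.

    Monomorphic probes and probes with more than two alleles are returned
    flagged not-applicable rather than raising.
    """
    called = probe_row[probe_row != NOCALL]
    alleles: dict[str, int] = {}
    for call in called:
        for al in call.split("/"):
            alleles[al] = alleles.get(al, 0) + 1
    if len(alleles) != 2:
        return HWEResult(probe_id, alleles, (0, 0, 0), float("nan"), float("nan"), False)
    # major = more frequent allele; ties broken lexicographically
    (major, minor) = sorted(alleles, key=lambda al: (-alleles[al], al))
    hom_minor = f"{minor}/{minor}"
    het = "/".join(sorted((major, minor)))
    counts = called.value_counts()
    n_mm = int(counts.get(f"{major}/{major}", 0))
    n_het = int(counts.get(het, 0))
    n_nn = int(counts.get(hom_minor, 0))
    n = n_mm + n_het + n_nn
    p = (2 * n_mm + n_het) / (2 * n)
    q = 1 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_mm, n_het, n_nn])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(sps.chi2.sf(chi2, df=1))
    return HWEResult(probe_id, alleles, (n_mm, n_het, n_nn), chi2, pval, True)


def hwe_screen(table: GenotypeTable) -> pd.DataFrame:
    """Run `hwe_test` over every probe; one row per probe."""
    rows = []
    for probe in table.probe_ids:
        r = hwe_test(table.probe_row(probe), probe)
        rows.append(
            {
                "probe_id": probe,
                "n_hom_major": r.genotype_counts[0],
                "n_het": r.genotype_counts[1],
                "n_hom_minor": r.genotype_counts[2],
                "chi_square": r.chi_square,
                "p": r.p_value,
                "applicable": r.applicable,
            }
        )
    return pd.DataFrame(rows)


def _per_class_category_counts(
    table: GenotypeTable, assignment: PhenotypeAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-category counts per probe, split by class (NoCall excluded)."""
    label_a, label_b = assignment.class_labels
    cols_a = [s for s in table.sample_ids if assignment.assignment.get(s) == label_a]
    cols_b = [s for s in table.sample_ids if assignment.assignment.get(s) == label_b]

    def _counts(cols):
        sub = table.calls[cols]
        stacked = sub.stack()
        stacked = stacked[stacked != NOCALL]
        return stacked.groupby(level=0).value_counts().unstack(fill_value=0)

    return _counts(cols_a), _counts(cols_b)


def screen_probes(
    table: GenotypeTable,
    assignment: PhenotypeAssignment,
    corrector: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exhaustive Fisher screening over every (probe, genotype) pair.

    Returns a DataFrame with columns probe_id, genotype, a, b, c, d,
    odds_ratio, p, p_adjusted, significant — sorted by adjusted p ascending
    (ties: raw p, then probe_id, then genotype), correction applied over the
    whole family of tests.
    """
    assignment.require_nonempty()
    counts_a, counts_b = _per_class_category_counts(table, assignment)
    rows = []
    for probe in table.probe_ids:
        ca = counts_a.loc[probe] if probe in counts_a.index else pd.Series(dtype=int)
        cb = counts_b.loc[probe] if probe in counts_b.index else pd.Series(dtype=int)
        total_a, total_b = int(ca.sum()), int(cb.sum())
        observed = sorted(
            set(ca[ca > 0].index) | set(cb[cb > 0].index)
        )
        for cat in observed:
            a = int(ca.get(cat, 0))
            c = int(cb.get(cat, 0))
            t = ContingencyTable2x2(a, total_a - a, c, total_b - c)
            rows.append(
                {
                    "probe_id": probe,
                    "genotype": cat,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "odds_ratio": odds_ratio(t),
                    "p": fisher_exact_two_sided(t),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "genotype", "a", "b", "c", "d", "odds_ratio", "p"],
    )
    if len(df):
        df["p_adjusted"] = correct_pvalues(df["p"], corrector)
        df["significant"] = df["p_adjusted"] <= alpha
        df = df.sort_values(
            ["p_adjusted", "p", "probe_id", "genotype"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    df.attrs["correction_family"] = "probe_x_genotype"
    df.attrs["corrector"] = corrector
    df.attrs["alpha"] = alpha
    return df
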