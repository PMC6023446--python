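"""Per-probe Kaplan-Meier screening of OS and PFS endpoints.

For every probe and every observed genotype category, samples split into
carriers of that genotype (group 1) versus samples with any other called
genotype (group 2); the two groups are compared with the standard two-group
log-rank test on the pooled event-time grid (ties resolved deaths before
censorings).  Probes are ranked by raw log-rank significance, mirroring how
the navigation panels order results; a Benjamini-Hochberg column is added
for convenience and labelled as such.  The hazard ratio is the model-free
(O1/E1)/(O2/E2) summary from the log-rank quantities — no Cox model is fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_dmet import NOCALL, GenotypeTable, SurvivalAnnotation
from .stats import correct_pvalues

ENDPOINTS = ("OS", "PFS")


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) after each distinct event time."""

    group_label: str
    event_times: np.ndarray   # strictly increasing distinct times with >=1 event
    survival: np.ndarray      # S(t) just after each event time
    n_at_risk: np.ndarray     # at-risk count at each event time
    n_subjects: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "n_at_risk": self.n_at_risk,
            }
        )

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    probe_id: str
    genotype_category: str
    endpoint: str
    chi_square: float
    p_value: float
    o1: float
    e1: float
    o2: float
    e2: float
    hazard_ratio: float
    median_1: float  # NaN when the curve never reaches 0.5
    median_2: float
    n1: int
    n2: int


def km_estimate(times, events, group_label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set just after their time, so a
    censoring tied with an event still counts in that event's risk set
    (deaths-before-censorings convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size
    event_times, surv, at_risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += e[j]
            j += 1
        ni = n - i
        if d > 0:
            s *= 1.0 - d / ni
            event_times.append(ti)
            surv.append(s)
            at_risk.append(ni)
        i = j
    return KMCurve(
        group_label,
        np.array(event_times),
        np.array(surv),
        np.array(at_risk, dtype=int),
        n_subjects=n,
        n_events=int(e.sum()),
    )


def median_survival(curve: KMCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN when S stays above 0.5."""
    below = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    return float(curve.event_times[below[0]]) if below.size else float("nan")


def logrank_test(times_1, events_1, times_2, events_2):
    """Two-group log-rank test.

    At each pooled distinct event time j: E1j = n1j*dj/nj and
    Vj = dj*(n1j/nj)*(1-n1j/nj)*(nj-dj)/(nj-1), the Vj term skipped when
    nj = 1.  Returns (chi_square, p, O1, E1, O2, E2); when no events occur
    in either group the statistic is not applicable and NaNs are returned.
    """
    t1 = np.asarray(times_1, dtype=float)
    e1 = np.asarray(events_1, dtype=int)
    t2 = np.asarray(times_2, dtype=float)
    e2 = np.asarray(events_2, dtype=int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    total_events = int(e1.sum() + e2.sum())
    if total_events == 0:
        nan = float("nan")
        return nan, nan, 0.0, 0.0, 0.0, 0.0
    pooled = np.concatenate([t1, t2])
    pooled_e = np.concatenate([e1, e2])
    grid = np.unique(pooled[pooled_e == 1])
    o1 = e1_exp = var = 0.0
    o2 = e2_exp = 0.0
    for tj in grid:
        n1j = int((t1 >= tj).sum())
        n2j = int((t2 >= tj).sum())
        nj = n1j + n2j
        d1j = int(e1[t1 == tj].sum())
        d2j = int(e2[t2 == tj].sum())
        dj = d1j + d2j
        if nj == 0 or dj == 0:
            continue
        o1 += d1j
        o2 += d2j
        e1_exp += n1j * dj / nj
        e2_exp += n2j * dj / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var <= 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o1 - e1_exp) ** 2 / var
        p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), float(p), float(o1), float(e1_exp), float(o2), float(e2_exp)


def hazard_ratio(o1: float, e1: float, o2: float, e2: float) -> float:
    """Model-free (O1/E1)/(O2/E2); inf/NaN under zero expected or observed."""
    if e1 <= 0 or e2 <= 0:
        return float("nan")
    r1, r2 = o1 / e1, o2 / e2
    if r2 == 0:
        return float("inf") if r1 > 0 else float("nan")
    return r1 / r2


def stratify_by_probe(probe_row: pd.Series, genotype_category: str):
    """Carrier samples of a genotype vs samples with any other called genotype."""
    called = probe_row[probe_row != NOCALL]
    if genotype_category not in set(called.values):
        raise ValueError(f"genotype {genotype_category!r} not observed at this probe")
    g1 = [s for s, c in called.items() if c == genotype_category]
    g2 = [s for s, c in called.items() if c != genotype_category]
    return g1, g2


def survival_screen(
    table: GenotypeTable,
    surv: SurvivalAnnotation,
    endpoint: str = "OS",
    collect_curves: bool = False,
):
    """Log-rank screen of every (probe, genotype) split for one endpoint.

    Only splits with both groups non-empty (after intersecting with the
    annotated samples) and at least one pooled event are tested.  Results
    are sorted by p ascending, ties by chi-square descending then probe_id
    and genotype.  Returns ``(frame, curves)`` where ``curves`` maps
    (probe, group-label) to a `KMCurve` when ``collect_curves`` is set.
    """
    data = surv.endpoint(endpoint)
    if len(data) < 2:
        raise ValueError("survival screening needs at least 2 annotated samples")
    annotated = set(data.index)
    rows = []
    curves: dict[tuple[str, str], KMCurve] = {}
    for probe in table.probe_ids:
        probe_row = table.probe_row(probe)
        called = probe_row[probe_row != NOCALL]
        called = called[[s in annotated for s in called.index]]
        categories = sorted(called.unique())
        if len(categories) < 2:
            continue
        if len(categories) == 2:
            # the two splits are mirror images; emit the comparison once
            categories = categories[:1]
        for cat in categories:
            g1 = called.index[called == cat]
            g2 = called.index[called != cat]
            d1, d2 = data.loc[g1], data.loc[g2]
            if d1["event"].sum() + d2["event"].sum() < 1:
                continue
            chi2, p, o1, e1v, o2, e2v = logrank_test(
                d1["time"], d1["event"], d2["time"], d2["event"]
            )
            c1 = km_estimate(d1["time"], d1["event"], f"{cat}")
            c2 = km_estimate(d2["time"], d2["event"], f"not-{cat}")
            if collect_curves:
                curves[(probe, c1.group_label)] = c1
                curves[(probe, c2.group_label)] = c2
            rows.append(
                {
                    "probe_id": probe,
                    "genotype": cat,
                    "n1": len(g1),
                    "n2": len(g2),
                    "O1": o1,
                    "E1": e1v,
                    "O2": o2,
                    "E2": e2v,
                    "chi_square": chi2,
                    "p": p,
                    "hazard_ratio": hazard_ratio(o1, e1v, o2, e2v),
                    "median_1": median_survival(c1),
                    "median_2": median_survival(c2),
                }
            )
    cols = [
        "probe_id", "genotype", "n1", "n2", "O1", "E1", "O2", "E2",
        "chi_square", "p", "p_bh", "hazard_ratio", "median_1", "median_2",
    ]
    df = pd.DataFrame(rows, columns=[c for c in cols if c != "p_bh"])
    if len(df):
        df["p_bh"] = correct_pvalues(df["p"].clip(lower=np.nextafter(0, 1)), "fdr_bh")
        df = df.sort_values(
            ["p", "chi_square", "probe_id", "genotype"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        df["p_bh"] = []
    df = df[cols]
    df.attrs["endpoint"] = endpoint
    df.attrs["p_bh_note"] = "BH-adjusted column added for convenience; ranking uses raw log-rank p"
    return df, curves
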