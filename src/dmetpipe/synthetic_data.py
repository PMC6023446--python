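"""Synthetic DMET-style datasets with planted, known effects.

The generator emulates the three inputs of a pharmacogenomics screening
study: a probes x samples genotype-call table, a two-class response
assignment (RESP / NoRESP) and per-sample OS/PFS survival annotations.
Background probes are biallelic and drawn under Hardy-Weinberg proportions
from allele frequencies sampled uniformly on a stated interval, so the HWE
test is calibrated on them by construction.  Three kinds of effects can be
planted with known ground truth:

* association — a probe whose carrier-genotype frequency differs between
  the two classes (e.g. 0.6 vs 0.1), the signal the Fisher screen targets;
* rule — class membership conditioned on joint carriage of an antecedent
  genotype set at a stated probability, the signal rule mining targets;
* survival — carriers of one genotype receive an elevated hazard (event
  times exponential, independent uniform censoring calibrated to a target
  censoring fraction), the signal the log-rank screen targets.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_dmet import (
    NOCALL,
    GenotypeTable,
    PhenotypeAssignment,
    SurvivalAnnotation,
)


@dataclass
class PlantedAssociation:
    probe_index: int
    carrier_frequency_class_a: float
    carrier_frequency_class_b: float
    genotype: str = "C/T"


@dataclass
class PlantedRule:
    antecedent: list[tuple[int, str]]  # (probe index, genotype)
    target_class: str
    probability: float  # P(target class | full antecedent carried)


@dataclass
class PlantedSurvival:
    probe_index: int
    genotype: str
    hazard_ratio: float


@dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    n_samples: int = 200
    n_probes: int = 200
    class_split: float = 0.5            # fraction assigned to class A
    maf_range: tuple[float, float] = (0.1, 0.4)
    nocall_rate: float = 0.02
    planted_associations: list[PlantedAssociation] = field(default_factory=list)
    planted_rules: list[PlantedRule] = field(default_factory=list)
    planted_survival: list[PlantedSurvival] = field(default_factory=list)
    baseline_hazard: float = 0.05       # events per month
    pfs_hazard: float = 0.08
    censoring_rate: float = 0.3
    class_labels: tuple[str, str] = ("RESP", "NoRESP")
    multiallelic_fraction: float = 0.0  # probes given a third allele (HWE n/a path)
    seed: int = 0

    def validate(self) -> None:
        for name in ("class_split", "nocall_rate", "censoring_rate", "multiallelic_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        planted = [pa.probe_index for pa in self.planted_associations]
        planted += [ps.probe_index for ps in self.planted_survival]
        for rule in self.planted_rules:
            planted += [i for i, _ in rule.antecedent]
            if not 0 <= rule.probability <= 1:
                raise ValueError("rule probability must lie in [0, 1]")
        assoc = [pa.probe_index for pa in self.planted_associations]
        if len(assoc) != len(set(assoc)):
            raise ValueError("planted association probe indices must be distinct")
        if planted and (min(planted) < 0 or max(planted) >= self.n_probes):
            raise ValueError("planted probe indices must lie in [0, n_probes)")


@dataclass
class TruthRecord:
    """Ground truth for every planted effect, keyed by probe_id."""

    associations: list[dict]
    rules: list[dict]
    survival: list[dict]

    def to_dict(self) -> dict:
        return {
            "associations": self.associations,
            "rules": self.rules,
            "survival": self.survival,
        }


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def _probe_id(i: int) -> str:
    return f"AM_{10000 + i}"


def _hw_genotypes(rng, ref: str, alt: str, q: float, n: int) -> np.ndarray:
    """Draw n biallelic genotypes under Hardy-Weinberg with alt frequency q."""
    p = 1 - q
    gt = rng.choice(3, size=n, p=[p * p, 2 * p * q, q * q])
    hom_ref = "/".join(sorted((ref, ref)))
    het = "/".join(sorted((ref, alt)))
    hom_alt = "/".join(sorted((alt, alt)))
    return np.array([hom_ref, het, hom_alt])[gt]


def _censor_horizon(hazard: float, target_rate: float) -> float:
    """Upper bound c of U(0, c) censoring giving the target censored fraction.

    For T ~ Exp(hazard) and C ~ U(0, c), P(C < T) = (1 - exp(-hazard*c)) /
    (hazard*c), which decreases from 1 to 0 in c; solved by bisection.
    """
    if target_rate <= 0:
        return float("inf")
    if target_rate >= 1:
        return np.finfo(float).tiny

    def f(c):
        return (1 - np.exp(-hazard * c)) / (hazard * c) - target_rate

    return brentq(f, 1e-9 / hazard, 1e6 / hazard)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[GenotypeTable, PhenotypeAssignment, SurvivalAnnotation, TruthRecord]:
    """Generate one dataset under ``spec``; fully reproducible from its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_probes
    samples = [f"S{i + 1:04d}" for i in range(n)]
    label_a, label_b = spec.class_labels

    calls = np.empty((m, n), dtype=object)
    probe_meta: dict[int, tuple[str, str]] = {}

    assoc_idx = {pa.probe_index: pa for pa in spec.planted_associations}
    surv_idx = {ps.probe_index: ps for ps in spec.planted_survival}
    # probes carrying a planted rule or survival genotype must actually be
    # able to produce it, so their allele pair is forced to match
    rule_geno = {ps.probe_index: ps.genotype for ps in spec.planted_survival}
    rule_geno.update({i: g for r in spec.planted_rules for i, g in r.antecedent})

    # background + rule-antecedent + survival probes first (class-independent)
    for i in range(m):
        if i in rule_geno:
            alleles = sorted(set(rule_geno[i].split("/")))
            if len(alleles) == 2:
                ref, alt = alleles
            else:
                ref = alleles[0]
                alt = next(b for b in "ACGT" if b != ref)
        else:
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        probe_meta[i] = (ref, alt)
        if i in assoc_idx:
            continue  # drawn per class below
        q = rng.uniform(*spec.maf_range)
        calls[i] = _hw_genotypes(rng, ref, alt, q, n)
        if spec.multiallelic_fraction and rng.random() < spec.multiallelic_fraction:
            third = next(b for b in "ACGT" if b not in (ref, alt))
            swap = rng.random(n) < 0.15
            calls[i][swap] = "/".join(sorted((ref, third)))

    # class assignment: conditioned on rule antecedents when rules are planted
    labels = np.where(rng.random(n) < spec.class_split, label_a, label_b)
    for rule in spec.planted_rules:
        carried = np.ones(n, dtype=bool)
        for probe_i, geno in rule.antecedent:
            carried &= calls[probe_i] == geno
        u = rng.random(n)
        other = label_b if rule.target_class == label_a else label_a
        labels[carried] = np.where(
            u[carried] < rule.probability, rule.target_class, other
        )

    # planted association probes: carrier frequency differs by class
    for i, pa in assoc_idx.items():
        alleles = sorted(set(pa.genotype.split("/")))
        if len(alleles) == 2:
            ref, alt = alleles
        else:
            ref = alleles[0]
            alt = next(b for b in "ACGT" if b != ref)
        probe_meta[i] = (ref, alt)
        carrier = pa.genotype
        hom_ref = "/".join(sorted((ref, ref)))
        hom_alt = "/".join(sorted((alt, alt)))
        filler = [g for g in (hom_ref, hom_alt) if g != carrier] or [hom_ref]
        freq = np.where(
            labels == label_a, pa.carrier_frequency_class_a, pa.carrier_frequency_class_b
        )
        is_carrier = rng.random(n) < freq
        fill = np.array(filler)[rng.integers(len(filler), size=n)]
        calls[i] = np.where(is_carrier, carrier, fill)

    # survival: exponential event times, hazard scaled for planted carriers
    os_hazard = np.full(n, spec.baseline_hazard)
    pfs_hazard = np.full(n, spec.pfs_hazard)
    for i, ps in surv_idx.items():
        carrier = calls[i] == ps.genotype
        os_hazard = np.where(carrier, os_hazard * ps.hazard_ratio, os_hazard)
        pfs_hazard = np.where(carrier, pfs_hazard * ps.hazard_ratio, pfs_hazard)
    os_t = rng.exponential(1.0 / os_hazard)
    pfs_t = rng.exponential(1.0 / pfs_hazard)
    pfs_t = np.minimum(pfs_t, os_t)  # progression precedes or equals death
    horizon = _censor_horizon(spec.baseline_hazard, spec.censoring_rate)
    censor = rng.uniform(0, horizon, size=n) if np.isfinite(horizon) else np.full(n, np.inf)
    os_event = (os_t <= censor).astype(int)
    os_time = np.minimum(os_t, censor)
    pfs_event = (pfs_t <= censor).astype(int)
    pfs_time = np.minimum(pfs_t, censor)

    # sprinkle NoCalls last so every stage sees realistic missingness
    if spec.nocall_rate > 0:
        mask = rng.random((m, n)) < spec.nocall_rate
        calls[mask] = NOCALL

    table = GenotypeTable(
        pd.DataFrame(calls, index=[_probe_id(i) for i in range(m)], columns=samples)
    )
    assignment = PhenotypeAssignment(
        spec.class_labels, dict(zip(samples, labels.tolist()))
    )
    surv = SurvivalAnnotation(
        pd.DataFrame(
            {
                "os_time": np.round(os_time, 6),
                "os_event": os_event.astype(float),
                "pfs_time": np.round(pfs_time, 6),
                "pfs_event": pfs_event.astype(float),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = TruthRecord(
        associations=[
            {
                "probe_id": _probe_id(pa.probe_index),
                "genotype": pa.genotype,
                "freq_class_a": pa.carrier_frequency_class_a,
                "freq_class_b": pa.carrier_frequency_class_b,
            }
            for pa in spec.planted_associations
        ],
        rules=[
            {
                "antecedent": [
                    {"probe_id": _probe_id(i), "genotype": g} for i, g in r.antecedent
                ],
                "target_class": r.target_class,
                "probability": r.probability,
            }
            for r in spec.planted_rules
        ],
        survival=[
            {
                "probe_id": _probe_id(ps.probe_index),
                "genotype": ps.genotype,
                "hazard_ratio": ps.hazard_ratio,
            }
            for ps in spec.planted_survival
        ],
    )
    return table, assignment, surv, truth


def worked_example_fixture():
    """Tiny hand-verifiable bundle: 8 probes x 12 samples, 6 RESP / 6 NoRESP.

    Every downstream quantity (Fisher tables, frequent itemsets, rules, KM
    curves, log-rank O/E) is small enough to verify by hand; the test suite
    carries those hand computations in its comments.

    Layout (samples R1..R6 are RESP, N1..N6 are NoRESP):
      P1 AM_00001 — perfect separator: RESP all C/T, NoRESP all C/C
      P2 AM_00002 — monomorphic A/A (preprocess removes it)
      P3 AM_00003 — 4/12 NoCall (removed at the 0.1 default threshold)
      P4 AM_00004 — G/G in R1..R5 and N1, A/G elsewhere
      P5 AM_00005 — T/T in R1..R4 + N1..N2, A/T elsewhere
      P6 AM_00006 — balanced A/C vs A/A, independent of class
      P7 AM_00007 — carriers G/T = {R1,R2,R3,N1,N2,N3}, rest A/A
      P8 AM_00008 — het A/G for odd samples, hom A/A for even
    """
    resp = [f"R{i}" for i in range(1, 7)]
    noresp = [f"N{i}" for i in range(1, 7)]
    samples = resp + noresp

    rows = {
        "AM_00001": ["C/T"] * 6 + ["C/C"] * 6,
        "AM_00002": ["A/A"] * 12,
        "AM_00003": ["A/A", "A/A", NOCALL, NOCALL, "A/G", "A/G",
                     NOCALL, NOCALL, "A/A", "A/G", "A/A", "A/A"],
        "AM_00004": ["G/G"] * 5 + ["A/G"] + ["G/G"] + ["A/G"] * 5,
        "AM_00005": ["T/T"] * 4 + ["A/T"] * 2 + ["T/T"] * 2 + ["A/T"] * 4,
        "AM_00006": ["A/C", "A/A"] * 6,
        "AM_00007": ["G/T"] * 3 + ["A/A"] * 3 + ["G/T"] * 3 + ["A/A"] * 3,
        "AM_00008": ["A/G", "A/A"] * 6,
    }
    table = GenotypeTable(pd.DataFrame(rows, index=samples).T)
    assignment = PhenotypeAssignment(
        ("RESP", "NoRESP"),
        {**{s: "RESP" for s in resp}, **{s: "NoRESP" for s in noresp}},
    )
    # months; carriers of AM_00007 G/T fail early, the rest late/censored
    surv = SurvivalAnnotation(
        pd.DataFrame(
            {
                "os_time": [3.0, 5.0, 8.0, 24.0, 30.0, 36.0,
                            2.0, 4.0, 6.0, 28.0, 32.0, 40.0],
                "os_event": [1, 1, 1, 0, 1, 0, 1, 1, 1, 0, 1, 0],
                "pfs_time": [2.0, 3.0, 6.0, 20.0, 24.0, 30.0,
                             1.0, 3.0, 5.0, 22.0, 26.0, 34.0],
                "pfs_event": [1, 1, 1, 0, 1, 0, 1, 1, 1, 0, 1, 0],
            },
            index=pd.Index(samples, name="sample_id"),
        ).astype(float)
    )
    return table, assignment, surv


def write_fixture_files(out_dir, table, assignment, surv, truth: TruthRecord | None = None):
    """Write the three input CSVs (+ truth.json) for CLI consumption."""
    import json
    from pathlib import Path

    from .io_dmet import write_genotype_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_table(table, out / "genotypes.csv")
    pd.Series(assignment.assignment, name="class").rename_axis("sample_id").to_csv(
        out / "classes.csv", header=False
    )
    surv.data.to_csv(out / "survival.csv")
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
    return out
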