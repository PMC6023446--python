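"""Reading, validation and writing of DMET-style genotype-call tables.

A genotype-call table is a delimited text file with probes as rows (IDs like
``AM_15502``), samples as columns, and literal diploid calls in the cells
("A/A", "A/G", ...) or the array's missing value ``NoCall``.  Calls are
stored canonically with the two allele symbols in a fixed total order, so
"G/A" and "A/G" compare equal.  Clinical annotations arrive as two small
side files: a two-class sample assignment (e.g. RESP / NoRESP) and an
optional per-sample survival annotation (OS/PFS time and event indicator).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NOCALL = "NoCall"

# allele symbol: a single IUPAC base, a deletion token "-", or a multi-base
# insertion string; the separator inside a call is "/".
_ALLELE_RE = re.compile(r"^(?:[ACGT]+|-)$")


class DmetFormatError(ValueError):
    """Raised for structurally invalid input files."""


def canonical_call(raw: str) -> tuple[str, bool]:
    """Canonicalize one genotype-cell string.

    Returns ``(call, parsed)`` where *call* is either the canonical
    "X/Y" form (allele symbols sorted under the fixed string order) or
    ``NOCALL``, and *parsed* is False when the cell was unparseable and
    was therefore coerced to ``NOCALL``.  ``NoCall`` itself parses cleanly.
    Half-calls such as "A/" are treated as unparseable.
    """
    s = str(raw).strip()
    if s.lower() in {"nocall", "no_call", "---", "nc"}:
        return NOCALL, True
    parts = s.upper().split("/")
    if len(parts) != 2:
        return NOCALL, False
    a, b = parts[0].strip(), parts[1].strip()
    if not (_ALLELE_RE.match(a) and _ALLELE_RE.match(b)):
        return NOCALL, False
    if b < a:
        a, b = b, a
    return f"{a}/{b}", True


@dataclass
class ParseReport:
    """Accounting of cells coerced to NoCall during parsing."""

    n_cells: int = 0
    n_unparseable: int = 0
    unparseable: list[tuple[str, str, str]] = field(default_factory=list)  # (probe, sample, raw)


@dataclass
class GenotypeTable:
    """Probes x samples matrix of canonical diploid calls.

    ``calls`` is a pandas DataFrame of strings indexed by probe_id with
    sample_id columns; every cell is either canonical "X/Y" or ``NOCALL``.
    """

    calls: pd.DataFrame
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        idx, cols = self.calls.index, self.calls.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DmetFormatError(f"duplicate probe IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DmetFormatError(f"duplicate sample IDs: {dups}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def probe_row(self, probe_id: str) -> pd.Series:
        return self.calls.loc[probe_id]

    def subset_probes(self, probe_ids) -> "GenotypeTable":
        return GenotypeTable(self.calls.loc[list(probe_ids)].copy())

    def equals(self, other: "GenotypeTable") -> bool:
        return self.calls.equals(other.calls)


@dataclass
class PhenotypeAssignment:
    """Two-class sample assignment (e.g. RESP vs NoRESP)."""

    class_labels: tuple[str, str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        a, b = self.class_labels
        if a == b:
            raise DmetFormatError("the two class labels must be distinct")
        bad = {s: l for s, l in self.assignment.items() if l not in self.class_labels}
        if bad:
            raise DmetFormatError(f"labels outside {self.class_labels}: {bad}")

    def samples_in(self, label: str) -> list[str]:
        return [s for s, l in self.assignment.items() if l == label]

    def class_sizes(self) -> tuple[int, int]:
        a, b = self.class_labels
        return len(self.samples_in(a)), len(self.samples_in(b))

    def require_nonempty(self) -> None:
        na, nb = self.class_sizes()
        if na == 0 or nb == 0:
            raise DmetFormatError(
                f"both classes must be non-empty, got sizes {self.class_labels[0]}={na}, "
                f"{self.class_labels[1]}={nb}"
            )


@dataclass
class SurvivalAnnotation:
    """Per-sample OS (and optionally PFS) time/event pairs.

    ``data`` is indexed by sample_id with columns os_time, os_event,
    pfs_time, pfs_event; PFS columns are NaN when absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        for tcol, ecol in (("os_time", "os_event"), ("pfs_time", "pfs_event")):
            t = d[tcol].dropna()
            if (t < 0).any() or not np.isfinite(t).all():
                raise DmetFormatError(f"{tcol} must be finite and >= 0")
            e = d[ecol].dropna()
            if not e.isin([0, 1]).all():
                raise DmetFormatError(f"{ecol} indicators must be 0 or 1")
        both = d.dropna(subset=["os_time", "pfs_time"])
        viol = both[both["pfs_time"] > both["os_time"]]
        if len(viol):
            warnings.warn(
                f"pfs_time exceeds os_time for samples {list(viol.index)}", stacklevel=2
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, which: str) -> pd.DataFrame:
        """Rows with complete (time, event) for endpoint 'OS' or 'PFS'."""
        which = which.upper()
        if which not in {"OS", "PFS"}:
            raise ValueError(f"unknown endpoint {which!r}")
        t, e = which.lower() + "_time", which.lower() + "_event"
        sub = self.data[[t, e]].dropna()
        return sub.rename(columns={t: "time", e: "event"})


def read_genotype_table(path, sep: str = ",", transpose: bool = False) -> GenotypeTable:
    """Read a delimited genotype-call table.

    First column holds probe IDs and the header row holds sample IDs;
    ``transpose=True`` flips that orientation.  Unparseable cells become
    NoCall and are counted in the table's ``parse_report``; structural
    problems (missing file, ragged rows, duplicate IDs) raise
    :class:`DmetFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise DmetFormatError(f"genotype table not found: {path}")
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if line:
                rows.append(line.split(sep))
    if len(rows) < 2:
        raise DmetFormatError(f"{path}: need a header and at least one data row")
    width = len(rows[0])
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise DmetFormatError(
                f"{path}: ragged row at line {i} ({len(r)} fields, expected {width})"
            )
    header = [c.strip() for c in rows[0][1:]]
    index = [r[0].strip() for r in rows[1:]]
    raw = pd.DataFrame([r[1:] for r in rows[1:]], index=index, columns=header)
    if transpose:
        raw = raw.T
    report = ParseReport(n_cells=raw.size)
    canon = raw.copy()
    for p in canon.index:
        for s in canon.columns:
            call, ok = canonical_call(canon.at[p, s])
            if not ok:
                report.n_unparseable += 1
                report.unparseable.append((p, s, str(raw.at[p, s])))
            canon.at[p, s] = call
    return GenotypeTable(canon, report)


def write_genotype_table(table: GenotypeTable, path, sep: str = ",") -> None:
    table.calls.to_csv(path, sep=sep, index_label="probe_id")


def read_class_file(
    path,
    sample_ids=None,
    class_labels: tuple[str, str] | None = None,
    on_unknown: str = "warn",
) -> PhenotypeAssignment:
    """Read a two-column ``sample_id,class`` file.

    Exactly two distinct labels must be observed.  When ``sample_ids`` (the
    genotype table's sample universe) is given, assignments for unknown
    samples are dropped with a warning (``on_unknown="warn"``) or raise
    (``on_unknown="error"``); a class left empty after the intersection is
    always an error.
    """
    path = Path(path)
    if not path.exists():
        raise DmetFormatError(f"class file not found: {path}")
    df = pd.read_csv(path, header=None, names=["sample_id", "label"], dtype=str,
                     comment="#", skipinitialspace=True)
    # tolerate an actual header line
    if df.iloc[0, 0].strip().lower() in {"sample_id", "sample"}:
        df = df.iloc[1:]
    df["sample_id"] = df["sample_id"].str.strip()
    df["label"] = df["label"].str.strip()
    labels = list(dict.fromkeys(df["label"]))  # first-appearance order
    if len(labels) != 2:
        raise DmetFormatError(f"expected exactly 2 class labels, found {sorted(set(labels))}")
    if class_labels is None:
        class_labels = (labels[0], labels[1])
    assignment = dict(zip(df["sample_id"], df["label"]))
    if sample_ids is not None:
        known = set(sample_ids)
        unknown = [s for s in assignment if s not in known]
        if unknown:
            if on_unknown == "error":
                raise DmetFormatError(f"class file samples not in genotype table: {unknown}")
            warnings.warn(
                f"dropping {len(unknown)} class-file sample(s) absent from the "
                f"genotype table: {unknown}", stacklevel=2,
            )
            assignment = {s: l for s, l in assignment.items() if s in known}
    pheno = PhenotypeAssignment(class_labels, assignment)
    pheno.require_nonempty()
    return pheno


def read_survival_file(path, sample_ids=None) -> SurvivalAnnotation:
    """Read a ``sample_id,os_time,os_event[,pfs_time,pfs_event]`` CSV."""
    path = Path(path)
    if not path.exists():
        raise DmetFormatError(f"survival file not found: {path}")
    df = pd.read_csv(path, dtype={0: str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    required = {"os_time", "os_event"}
    if not required.issubset(df.columns):
        raise DmetFormatError(f"survival file needs columns {sorted(required)}")
    for col in ("pfs_time", "pfs_event"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("sample_id")[["os_time", "os_event", "pfs_time", "pfs_event"]]
    df = df.astype(float)
    if sample_ids is not None:
        known = set(sample_ids)
        unknown = [s for s in df.index if s not in known]
        if unknown:
            warnings.warn(
                f"dropping {len(unknown)} survival sample(s) absent from the "
                f"genotype table: {unknown}", stacklevel=2,
            )
            df = df.loc[[s for s in df.index if s in known]]
    return SurvivalAnnotation(df)


def write_results_bundle(results, out_dir) -> dict:
    """Write every tabular artifact of a pipeline run plus run_manifest.json.

    ``results`` is an `engine.PipelineResults`.  Output is deterministic:
    identical inputs and configuration produce byte-identical files.
    Returns the manifest dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, int] = {}

    def _emit(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
        inventory[name] = len(df)

    if results.preprocess_report is not None:
        _emit("preprocess_report.csv", results.preprocess_report.to_frame())
    if results.distribution is not None:
        d = results.distribution.counts.reset_index(names="probe_id")
        _emit("heatmap_matrix.csv", d)
    if results.fisher is not None:
        _emit("fisher_results.csv", results.fisher)
    if results.hwe is not None:
        _emit("hwe_results.csv", results.hwe)
    if results.rules is not None:
        from .rulemining import rules_frame

        for label, ruleset in results.rules.items():
            _emit(f"rules_{label}.csv", rules_frame(ruleset))
    for endpoint, df in (results.survival or {}).items():
        _emit(f"survival_{endpoint}.csv", df)
    for (probe, group), curve in (results.km_curves or {}).items():
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", f"{probe}_{group}")
        _emit(f"km_curve_{safe}.csv", curve.to_frame())

    manifest = {
        "config": results.config_echo,
        "stages": results.stage_status,
        "stage_seconds": results.stage_seconds,  # informational; varies run to run
        "files": inventory,
        "version": _package_version(),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("dmetpipe")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
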