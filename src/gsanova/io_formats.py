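"""Readers and writers for the tabular formats the tool touches.

Count tables follow the htseq-count dialect: tab-separated, one gene per
row, first column the gene identifier.  A merged multi-sample table carries
a header row of sample names; per-sample two-column files (no header) can
be merged with :func:`merge_count_files`.  Gene sets are read and written
in the Broad GMT dialect, and sample-to-group assignments as a two-column
TSV.  All text I/O is UTF-8 and tolerant of ``\\n`` / ``\\r\\n`` endings.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "read_count_table",
    "write_count_table",
    "merge_count_files",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_enrichment_table",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Non-negative integer gene × sample matrix with identifiers.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    counts : ndarray of int, shape (n_genes, n_samples)
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = [k for k, c in Counter(ids).items() if c > 1]
            if dupes:
                raise ValueError(f"duplicate {label} id(s): {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        """Return a copy restricted to ``keep`` (order of ``keep`` preserved)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in keep]
        return CountMatrix(list(self.gene_ids), list(keep), self.counts[:, idx])


@dataclass
class SampleDesign:
    """Ordered sample → group assignment defining k groups of sizes n_i."""

    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        dupes = [k for k, c in Counter(self.sample_ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate sample id(s): {dupes[:5]}")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group: {missing[:5]}")
        if self.k < 2:
            raise ValueError(f"need at least 2 groups, got {self.k}")

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = Counter(self.group_of[s] for s in self.sample_ids)
        return {g: sizes[g] for g in self.groups}

    def labels(self) -> np.ndarray:
        """Integer group codes aligned with ``sample_ids`` (0..k-1)."""
        code = {g: i for i, g in enumerate(self.groups)}
        return np.array([code[self.group_of[s]] for s in self.sample_ids])

    def subset(self, keep: Sequence[str]) -> "SampleDesign":
        keep_set = set(keep)
        ids = [s for s in self.sample_ids if s in keep_set]
        return SampleDesign(ids, {s: self.group_of[s] for s in ids})


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, preserving file order."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        members = set(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description


def _open_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    # splitlines handles \n and \r\n uniformly
    return text.splitlines()


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a merged htseq-count-style table (header row of sample names).

    ``__``-prefixed bookkeeping rows (``__no_feature``, ``__ambiguous``, ...)
    are dropped; the number dropped is logged.  Row order of the remaining
    genes is preserved.
    """
    lines = [ln for ln in _open_lines(path) if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header and at least one gene row")
    header = lines[0].split("\t")
    sample_ids = header[1:] if header[0] in ("", "gene", "gene_id") else header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header row has no sample columns")
    ncol = len(header)
    gene_ids: list[str] = []
    rows: list[list[int]] = []
    n_summary = 0
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        gid = fields[0]
        if gid.startswith("__"):
            n_summary += 1
            continue
        try:
            row = [int(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer count: {exc}") from exc
        if any(c < 0 for c in row):
            raise ParseError(f"{path}: line {lineno}: negative count")
        gene_ids.append(gid)
        rows.append(row)
    if n_summary:
        logger.info("dropped %d '__'-prefixed summary row(s) from %s", n_summary, path)
    dupes = [g for g, c in Counter(gene_ids).items() if c > 1]
    if dupes:
        raise ParseError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    if not gene_ids:
        raise ParseError(f"{path}: no gene rows after dropping summary rows")
    return CountMatrix(gene_ids, list(sample_ids), np.array(rows, dtype=np.int64))


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    """Write a merged count table readable by :func:`read_count_table`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(cm.sample_ids) + "\n")
        for gid, row in zip(cm.gene_ids, cm.counts):
            fh.write(gid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def merge_count_files(paths: Sequence[str | Path], sample_ids: Sequence[str] | None = None) -> CountMatrix:
    """Join per-sample two-column htseq-count outputs on gene id.

    Every file must cover exactly the same gene universe; a mismatch is an
    error rather than an implicit outer join.  ``sample_ids`` defaults to
    the file stems.
    """
    if not paths:
        raise ValueError("no files to merge")
    if sample_ids is None:
        sample_ids = [Path(p).stem for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids length must match number of files")
    ref_genes: list[str] | None = None
    cols: list[np.ndarray] = []
    for path in paths:
        genes: list[str] = []
        vals: list[int] = []
        for lineno, ln in enumerate(_open_lines(path), start=1):
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            if fields[0].startswith("__"):
                continue
            genes.append(fields[0])
            try:
                vals.append(int(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer count") from exc
        if ref_genes is None:
            ref_genes = genes
        elif genes != ref_genes:
            raise ParseError(f"{path}: gene universe differs from {paths[0]}")
        cols.append(np.array(vals, dtype=np.int64))
    assert ref_genes is not None
    return CountMatrix(ref_genes, list(sample_ids), np.column_stack(cols))


def read_design(path: str | Path, exclude: Sequence[str] = ()) -> SampleDesign:
    """Read a two-column ``sample\\tgroup`` table (header optional).

    ``exclude`` removes samples (e.g. QC failures) before the design is
    validated; at least two groups must remain.
    """
    lines = [ln for ln in _open_lines(path) if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty design file")
    if lines[0].split("\t")[0].lower() in ("sample", "sample_id"):
        lines = lines[1:]
    if not lines:
        raise ParseError(f"{path}: design file has a header but no rows")
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    excl = set(exclude)
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        sid, grp = fields
        if sid in group_of:
            raise ParseError(f"{path}: sample {sid!r} listed twice")
        if sid in excl:
            continue
        sample_ids.append(sid)
        group_of[sid] = grp
    if not sample_ids:
        raise ParseError(f"{path}: no samples remain after exclusion")
    return SampleDesign(sample_ids, group_of)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in design.sample_ids:
            fh.write(f"{s}\t{design.group_of[s]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are collapsed with a logged warning;
    a duplicate set name is an error.
    """
    coll = GeneSetCollection()
    for lineno, ln in enumerate(_open_lines(path), start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        members = [m for m in members if m]
        uniq = set(members)
        if len(uniq) < len(members):
            logger.warning(
                "%s: line %d: set %r has %d duplicate member(s), deduplicated",
                path, lineno, name, len(members) - len(uniq),
            )
        try:
            coll.add(name, uniq, desc)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if len(coll) == 0:
        raise ParseError(f"{path}: no gene sets found")
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


ENRICHMENT_COLUMNS = [
    "set_name",
    "set_size",
    "raw_score",
    "standardized_score",
    "p_nominal",
    "p_pooled",
    "q_value",
    "significant",
]


def write_enrichment_table(results: Sequence, path: str | Path) -> None:
    """Write enrichment results as TSV, sorted by q-value then pooled p."""
    if not results:
        raise ValueError("no enrichment results to write")
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "set_size": [r.set_size_in_universe for r in results],
            "raw_score": [r.raw_score for r in results],
            "standardized_score": [r.standardized_score for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "p_pooled": [r.p_pooled for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    df = df.sort_values(["q_value", "p_pooled"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
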