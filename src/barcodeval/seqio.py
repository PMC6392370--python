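"""Sequence, alignment and taxon-map containers plus the file plumbing.

FASTA parsing is delegated to Biopython after a light structural pre-scan
(the pre-scan exists only to report malformed files with a line number).
Trees travel as newick via dendropy with underscores left unquoted.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

# IUPAC nucleotide codes, gap and missing symbols.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class TaxonMapError(ValueError):
    """Raised for schema or consistency problems in a taxon map."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (stored upper-case, U mapped to T)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"sequence for {self.id!r} is empty")
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def degapped(self) -> str:
        """Sequence with alignment gaps removed."""
        return self.sequence.replace("-", "")


class Alignment:
    """An ordered set of equal-length sequence rows.

    Parameters
    ----------
    records:
        At least two :class:`SequenceRecord` of identical length.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self.records: list[SequenceRecord] = records
        self.length: int = lengths.pop()
        self._by_id = {r.id: r for r in records}

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        """New alignment restricted to ``keep_ids`` (original row order kept)."""
        keep = set(keep_ids)
        return Alignment([r for r in self.records if r.id in keep])


class ConcatenatedAlignment(Alignment):
    """Alignment produced by region concatenation; keeps per-region spans."""

    def __init__(self, records: Sequence[SequenceRecord],
                 region_spans: Mapping[str, tuple[int, int]]):
        super().__init__(records)
        #: region name -> half-open column interval [start, end)
        self.region_spans: dict[str, tuple[int, int]] = dict(region_spans)


@dataclass(frozen=True)
class TaxonEntry:
    sequence_id: str
    species: str
    individual: str
    is_outgroup: bool = False


class TaxonMap:
    """Assignment of sequence ids to species labels, individuals and outgroup flags."""

    def __init__(self, entries: Sequence[TaxonEntry]):
        entries = list(entries)
        ids = [e.sequence_id for e in entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TaxonMapError(f"duplicate sequence ids in taxon map: {dup}")
        if not any(not e.is_outgroup for e in entries):
            raise TaxonMapError("taxon map must contain at least one non-outgroup entry")
        for e in entries:
            if not e.species:
                raise TaxonMapError(f"empty species label for {e.sequence_id!r}")
        self.entries: list[TaxonEntry] = entries
        self._by_id = {e.sequence_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def species_of(self, seq_id: str) -> str:
        return self._by_id[seq_id].species

    def individual_of(self, seq_id: str) -> str:
        return self._by_id[seq_id].individual

    def is_outgroup(self, seq_id: str) -> bool:
        return self._by_id[seq_id].is_outgroup

    @property
    def outgroup_ids(self) -> list[str]:
        return [e.sequence_id for e in self.entries if e.is_outgroup]

    @property
    def ingroup_ids(self) -> list[str]:
        return [e.sequence_id for e in self.entries if not e.is_outgroup]

    def species_members(self, include_outgroups: bool = False) -> dict[str, list[str]]:
        """Species label -> sequence ids, in map order."""
        out: dict[str, list[str]] = {}
        for e in self.entries:
            if e.is_outgroup and not include_outgroups:
                continue
            out.setdefault(e.species, []).append(e.sequence_id)
        return out

    def restricted_to(self, seq_ids: Iterable[str]) -> "TaxonMap":
        keep = set(seq_ids)
        return TaxonMap([e for e in self.entries if e.sequence_id in keep])


# ---------------------------------------------------------------------------
# readers


def _prescan_fasta(path: Path) -> None:
    """Report structural problems (with line numbers) before real parsing."""
    seen_header = False
    header_line = 0
    have_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                if seen_header and not have_seq:
                    raise FastaParseError(
                        f"{path}: empty record for header at line {header_line}"
                    )
                seen_header = True
                header_line = lineno
                have_seq = False
            else:
                if not seen_header:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                have_seq = True
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    if not have_seq:
        raise FastaParseError(f"{path}: empty record for header at line {header_line}")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The token before the first whitespace of each header becomes the id,
    the remainder the description. Sequences are upper-cased and U→T.
    Duplicate ids raise ``FastaParseError``.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def read_alignment(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA file (all rows equal length)."""
    return Alignment(read_fasta(path))


REQUIRED_TAXON_COLUMNS = ("sequence_id", "species", "individual", "outgroup")
_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def read_taxon_map(path: str | os.PathLike) -> TaxonMap:
    """Read a TSV taxon map with columns sequence_id, species, individual, outgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_TAXON_COLUMNS if c not in df.columns]
    if missing:
        raise TaxonMapError(f"{path}: missing required column(s) {missing}")
    entries = []
    for row in df.itertuples(index=False):
        flag = str(row.outgroup).strip().lower()
        if flag in _TRUE:
            og = True
        elif flag in _FALSE:
            og = False
        else:
            raise TaxonMapError(
                f"{path}: cannot parse outgroup flag {row.outgroup!r} "
                f"for {row.sequence_id!r}"
            )
        entries.append(
            TaxonEntry(
                sequence_id=str(row.sequence_id).strip(),
                species=str(row.species).strip(),
                individual=str(row.individual).strip(),
                is_outgroup=og,
            )
        )
    return TaxonMap(entries)


def write_taxon_map(taxa: TaxonMap, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (e.sequence_id, e.species, e.individual, str(e.is_outgroup).lower())
            for e in taxa.entries
        ],
        columns=list(REQUIRED_TAXON_COLUMNS),
    )
    _atomic_write(path, df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# concatenation


def concatenate_alignments(
    alignments: Sequence[tuple[str, Alignment]],
    sample_key: Mapping[str, str],
) -> ConcatenatedAlignment:
    """Concatenate per-region alignments into one matrix, joined on individual.

    Rows are individuals present in *all* supplied regions (complete-case /
    intersection policy); region blocks are appended in the given order and
    the resulting column spans are kept on the returned object. Row ids of
    the output are individual ids, since the per-region sequences of one
    individual generally carry distinct accessions.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    per_region: list[dict[str, SequenceRecord]] = []
    for name, aln in alignments:
        mapping: dict[str, SequenceRecord] = {}
        for rec in aln:
            try:
                ind = sample_key[rec.id]
            except KeyError:
                raise ValueError(
                    f"sequence {rec.id!r} in region {name!r} missing from sample key"
                ) from None
            if ind in mapping:
                raise ValueError(
                    f"individual {ind!r} appears more than once in region {name!r}"
                )
            mapping[ind] = rec
        per_region.append(mapping)

    common = set(per_region[0])
    for mapping in per_region[1:]:
        common &= set(mapping)
    if not common:
        raise ValueError("no individual is present in every region")
    # preserve the row order of the first region
    order = [ind for ind in per_region[0] if ind in common]

    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for (name, aln) in alignments:
        spans[name] = (offset, offset + aln.length)
        offset += aln.length

    rows = []
    for ind in order:
        seq = "".join(mapping[ind].sequence for mapping in per_region)
        rows.append(SequenceRecord(ind, seq))
    return ConcatenatedAlignment(rows, spans)


# ---------------------------------------------------------------------------
# ITS2 extraction


@dataclass
class ExtractionResult:
    """Outcome of motif-anchored sub-region extraction."""

    records: list[SequenceRecord] = field(default_factory=list)
    #: sequence id -> failure reason for inputs where extraction failed
    failures: dict[str, str] = field(default_factory=dict)


# Default anchor motifs: conserved 3' flank of 5.8S and 5' flank of 28S/26S
# bordering the ITS2 spacer in plant nuclear rDNA.
DEFAULT_MOTIF_5P = "GACTCTCGGCAACGGATA"
DEFAULT_MOTIF_3P = "TTGCGCGACGCCCAGGCA"


def _best_hits(haystack: str, needle: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) pairs achieving the minimal Hamming distance
    at or below ``max_mismatch``; empty if no window qualifies."""
    n, m = len(haystack), len(needle)
    best = max_mismatch + 1
    hits: list[tuple[int, int]] = []
    for start in range(n - m + 1):
        mm = 0
        for a, b in zip(haystack[start:start + m], needle):
            if a != b:
                mm += 1
                if mm > best:
                    break
        if mm < best:
            best = mm
            hits = [(start, mm)]
        elif mm == best:
            hits.append((start, mm))
    return hits if best <= max_mismatch else []


def extract_its2(
    its_records: Sequence[SequenceRecord],
    motif_5p: str = DEFAULT_MOTIF_5P,
    motif_3p: str = DEFAULT_MOTIF_3P,
    max_mismatch: int = 1,
) -> ExtractionResult:
    """Trim full ITS sequences to the ITS2 spacer between two anchor motifs.

    The 5' motif marks the 3' end of the 5.8S gene, the 3' motif the 5' end of
    the 28S/26S gene; the extracted sub-region lies strictly between the best
    hit of each motif, searched on the gap-free sequence with at most
    ``max_mismatch`` Hamming mismatches. Inputs whose motifs cannot be located
    unambiguously are reported in ``failures`` rather than silently dropped.
    """
    if not motif_5p or not motif_3p:
        raise ValueError("anchor motifs must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    result = ExtractionResult()
    for rec in its_records:
        seq = rec.degapped()
        hits5 = _best_hits(seq, motif_5p, max_mismatch)
        hits3 = _best_hits(seq, motif_3p, max_mismatch)
        if not hits5:
            result.failures[rec.id] = "5' anchor motif not found"
            continue
        if not hits3:
            result.failures[rec.id] = "3' anchor motif not found"
            continue
        if len(hits5) > 1:
            result.failures[rec.id] = "5' anchor motif ambiguous (tied best hits)"
            continue
        if len(hits3) > 1:
            result.failures[rec.id] = "3' anchor motif ambiguous (tied best hits)"
            continue
        start = hits5[0][0] + len(motif_5p)
        end = hits3[0][0]
        if end <= start:
            result.failures[rec.id] = "3' anchor motif precedes 5' anchor motif"
            continue
        result.records.append(SequenceRecord(rec.id, seq[start:end], rec.description))
    return result


# ---------------------------------------------------------------------------
# writers


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_fasta(records: Iterable[SequenceRecord] | Alignment,
                path: str | os.PathLike, width: int = 70) -> None:
    """Write records as FASTA (atomically: temp file + rename)."""
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        lines.append(header)
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i:i + width])
    _atomic_write(path, "\n".join(lines) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths at full precision."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    _atomic_write(path, tree_to_newick(tree) + "\n")


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_outputs(
    records: Iterable[SequenceRecord] | Alignment | None,
    tree: dendropy.Tree | None,
    prefix: str | os.PathLike,
) -> list[Path]:
    """Write sequence and/or tree outputs under a common path prefix.

    ``<prefix>.fasta`` and/or ``<prefix>.nwk`` are produced; both writes are
    atomic and round-trip losslessly through :func:`read_fasta` /
    :func:`read_newick`.
    """
    prefix = Path(prefix)
    written: list[Path] = []
    if records is not None:
        p = prefix.with_suffix(".fasta")
        write_fasta(records, p)
        written.append(p)
    if tree is not None:
        p = prefix.with_suffix(".nwk")
        write_newick(tree, p)
        written.append(p)
    if not written:
        raise ValueError("nothing to write")
    return written
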