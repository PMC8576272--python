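"""Readers, writers and validation for the file formats the pipeline touches.

Four inputs describe a protein: its sequence (FASTA), an evolutionary
profile (the ASCII position-specific scoring matrix written by PSI-BLAST's
``-out_ascii_pssm`` option), a per-residue secondary-structure assignment
(DSSP output, or a bare 9-state string), and per-residue binary
interaction-site labels (TSV).  :func:`assemble_record` reconciles the four
into a validated :class:`ProteinRecord`.

Conventions, fixed package-wide:

* residue positions are 0-based;
* amino-acid columns follow :data:`AA_ORDER` (alphabetical one-letter
  codes); PSSM files in PSI-BLAST's own column order are remapped on read;
* any letter outside the 20 standard codes becomes ``'X'``;
* the nine secondary-structure states are :data:`SS_ORDER`, with ``'-'``
  (no secondary structure) reserved for padding/unresolved residues and the
  blank DSSP code mapped to ``'L'`` (loop or irregular).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Run-wide amino-acid column order (alphabetical one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Nine secondary-structure states: alpha-helix, 3_10-helix, pi-helix,
#: beta-bridge, beta-strand, beta-turn, bend, loop/irregular, none.
SS_ORDER = "HGIBETSL-"
SS_INDEX = {s: i for i, s in enumerate(SS_ORDER)}

#: Column order PSI-BLAST prints in its ASCII PSSM.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Sentinel for a residue with no label.
LABEL_MISSING = -1


class FormatError(ValueError):
    """A file did not match the expected format."""


@dataclass
class PssmMatrix:
    """L x 20 log-odds profile aligned to a sequence.

    ``scores`` rows follow sequence positions (0-based); columns follow
    ``column_order`` (:data:`AA_ORDER` for every matrix produced by this
    package).
    """

    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM must have exactly 20 columns, got shape {self.scores.shape}"
            )
        if len(self.column_order) != 20 or set(self.column_order) != set(AA_ORDER):
            raise ValueError("column_order must be a permutation of the 20 amino acids")

    def __len__(self) -> int:
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PssmMatrix):
            return NotImplemented
        return (
            self.column_order == other.column_order
            and self.scores.shape == other.scores.shape
            and np.array_equal(self.scores, other.scores)
        )


@dataclass
class ProteinRecord:
    """A protein sequence with optional profile, secondary structure and labels.

    ``labels`` is an int array of length L with entries 0, 1 or
    :data:`LABEL_MISSING`; missing residues are excluded from training and
    evaluation downstream.
    """

    id: str
    sequence: str
    pssm: PssmMatrix | None = None
    ss9: str | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Re-check every structural invariant; raise ``ValueError`` on violation."""
        L = len(self.sequence)
        if L < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(AA_ORDER + "X")
        if bad:
            raise ValueError(f"{self.id}: letters outside the 21-letter alphabet: {sorted(bad)}")
        if self.pssm is not None and len(self.pssm) != L:
            raise ValueError(
                f"{self.id}: length mismatch: sequence has {L} residues, PSSM has {len(self.pssm)} rows"
            )
        if self.ss9 is not None:
            if len(self.ss9) != L:
                raise ValueError(
                    f"{self.id}: length mismatch: sequence has {L} residues, ss9 has {len(self.ss9)}"
                )
            bad_ss = set(self.ss9) - set(SS_ORDER)
            if bad_ss:
                raise ValueError(f"{self.id}: unknown secondary-structure codes: {sorted(bad_ss)}")
        if self.labels is not None:
            if self.labels.shape != (L,):
                raise ValueError(
                    f"{self.id}: length mismatch: sequence has {L} residues, labels has {self.labels.shape}"
                )
            ok = np.isin(self.labels, (0, 1, LABEL_MISSING))
            if not ok.all():
                raise ValueError(f"{self.id}: labels must be 0, 1 or missing")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinRecord):
            return NotImplemented
        if (self.id, self.sequence, self.ss9) != (other.id, other.sequence, other.ss9):
            return False
        if (self.pssm is None) != (other.pssm is None) or (
            self.pssm is not None and self.pssm != other.pssm
        ):
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or np.array_equal(self.labels, other.labels)


def _clean_sequence(seq: str) -> str:
    return "".join(c if c in AA_INDEX else "X" for c in seq.upper())


def parse_fasta(text: str) -> list[ProteinRecord]:
    """Parse multi-entry FASTA text into bare :class:`ProteinRecord` objects.

    Sequences are uppercased and non-standard letters mapped to ``'X'``.
    Entry order is preserved.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _clean_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"zero-length sequence for header '{rec.id}'")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError("no sequences")
    return records


def write_fasta(records: list[ProteinRecord], width: int = 60) -> str:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def parse_pssm(text: str) -> PssmMatrix:
    """Parse PSI-BLAST ``-out_ascii_pssm`` output into a :class:`PssmMatrix`.

    Layout: two header lines, a column-header line naming the 20 amino
    acids, one line per residue (rank, residue letter, 20 log-odds
    integers, further columns ignored), then trailer lines.  The file's own
    column order is remapped to :data:`AA_ORDER`.
    """
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in AA_INDEX for t in toks[:20]):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError("no PSSM column-header line found")
    file_order = "".join(lines[header_idx].split()[:20])
    if set(file_order) != set(AA_ORDER):
        raise FormatError(f"column header is not a permutation of the 20 amino acids: {file_order}")

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        toks = line.split()
        if not toks:
            break  # blank line terminates the residue block
        if not toks[0].isdigit():
            break  # trailer (Lambda/K statistics)
        if len(toks) < 22:
            raise FormatError(f"line {lineno}: expected 20 score columns, got {len(toks) - 2}")
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric score: {exc}") from None
        rows.append(scores)
    if not rows:
        raise FormatError("PSSM contains no residue rows")

    raw = np.asarray(rows, dtype=float)
    remap = [file_order.index(a) for a in AA_ORDER]
    return PssmMatrix(scores=raw[:, remap], column_order=AA_ORDER)


def write_pssm(pssm: PssmMatrix, sequence: str) -> str:
    """Serialize a PSSM in the PSI-BLAST ASCII dialect :func:`parse_pssm` reads.

    Emits the log-odds block in PSI-BLAST's native column order followed by
    a placeholder percentage block, mirroring the real tool's layout.
    """
    if len(pssm) != len(sequence):
        raise ValueError(f"PSSM has {len(pssm)} rows but sequence has {len(sequence)} residues")
    remap = [pssm.column_order.index(a) for a in PSIBLAST_AA_ORDER]
    block = pssm.scores[:, remap]
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted, and rounded",
        "            " + "  ".join(PSIBLAST_AA_ORDER) + "   " + "  ".join(PSIBLAST_AA_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(sequence, block), start=1):
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        pct = " ".join("  0" for _ in range(20))
        out.append(f"{i:5d} {aa}  {scores}  {pct}  0.00 0.00")
    out += ["", "                      K         Lambda", "Standard Ungapped    0.1377     0.3190", ""]
    return "\n".join(out)


_DSSP_SENTINEL = "  #  RESIDUE"
_DSSP_CODES = set("HGIBETS")


def parse_dssp(text: str) -> str:
    """Extract the per-residue 9-state string from a DSSP output file.

    DSSP's eight structure codes H,G,I,B,E,T,S map to themselves and the
    blank code to ``'L'``; chain-break rows (``'!'``) are skipped.  The
    ninth state ``'-'`` never appears here — it is reserved for residues
    missing from DSSP, filled in by :func:`assemble_record`.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith(_DSSP_SENTINEL):
            start = i + 1
            break
    if start is None:
        raise FormatError("not a DSSP file: missing '  #  RESIDUE' header line")
    states = []
    for line in lines[start:]:
        if len(line) < 17:
            continue
        aa = line[13]
        if aa == "!":
            continue  # chain break
        code = line[16]
        states.append(code if code in _DSSP_CODES else "L")
    if not states:
        raise FormatError("DSSP file contains no residue rows")
    return "".join(states)


def write_dssp(ss: str, sequence: str | None = None) -> str:
    """Serialize a 9-state string as a minimal DSSP-shaped file (test fixtures).

    ``'-'`` states are rendered as blank structure codes; real DSSP output
    carries many more columns, all ignored by :func:`parse_dssp`.
    """
    seq = sequence or "A" * len(ss)
    out = [
        "==== Secondary Structure Definition by the program DSSP ====",
        _DSSP_SENTINEL + " AA STRUCTURE BP1 BP2  ACC",
    ]
    for i, (code, aa) in enumerate(zip(ss, seq), start=1):
        c = code if code in _DSSP_CODES else " "
        out.append(f"{i:5d}{i:5d} A {aa}  {c}" + " " * 20)
    return "\n".join(out) + "\n"


def parse_labels(text: str) -> dict[str, dict[int, int]]:
    """Parse a label TSV (``id<TAB>position<TAB>{0,1}``, positions 0-based).

    Returns a sparse per-protein map; duplicate consistent lines are
    idempotent, conflicting duplicates raise.
    """
    labels: dict[str, dict[int, int]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
        pid, pos_s, lab_s = parts
        try:
            pos = int(pos_s)
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer position '{pos_s}'") from None
        if pos < 0:
            raise FormatError(f"line {lineno}: negative position {pos}")
        if lab_s not in ("0", "1"):
            raise FormatError(f"line {lineno}: label must be 0 or 1, got '{lab_s}'")
        lab = int(lab_s)
        prev = labels.setdefault(pid, {}).get(pos)
        if prev is not None and prev != lab:
            raise FormatError(f"line {lineno}: conflicting duplicate label for ({pid}, {pos})")
        labels[pid][pos] = lab
    return labels


def write_labels(records: list[ProteinRecord]) -> str:
    lines = []
    for rec in records:
        if rec.labels is None:
            continue
        for pos, lab in enumerate(rec.labels):
            if lab != LABEL_MISSING:
                lines.append(f"{rec.id}\t{pos}\t{int(lab)}")
    return "\n".join(lines) + ("\n" if lines else "")


def assemble_record(
    entry: ProteinRecord,
    pssm: PssmMatrix | None = None,
    ss9: str | None = None,
    labels: dict[int, int] | None = None,
    missing_label: int = LABEL_MISSING,
) -> ProteinRecord:
    """Reconcile the parts of one protein into a validated record.

    A too-short ss9 is right-padded with ``'-'``; PSSM row count must equal
    the sequence length exactly; label positions beyond the sequence raise.
    Unlabelled positions receive ``missing_label`` (default: excluded from
    training and evaluation; pass ``0`` to treat them as non-sites).
    """
    L = len(entry.sequence)
    if pssm is not None and len(pssm) != L:
        raise ValueError(
            f"{entry.id}: length mismatch: sequence has {L} residues, PSSM has {len(pssm)} rows"
        )
    if ss9 is not None:
        if len(ss9) > L:
            raise ValueError(
                f"{entry.id}: length mismatch: sequence has {L} residues, ss9 has {len(ss9)}"
            )
        ss9 = ss9 + "-" * (L - len(ss9))
    dense = None
    if labels is not None:
        dense = np.full(L, missing_label, dtype=np.int64)
        for pos, lab in labels.items():
            if pos >= L:
                raise ValueError(f"{entry.id}: label position {pos} beyond sequence length {L}")
            dense[pos] = lab
    rec = ProteinRecord(id=entry.id, sequence=entry.sequence, pssm=pssm, ss9=ss9, labels=dense)
    rec.validate()
    return rec


def load_manifest(path: str | Path) -> list[ProteinRecord]:
    """Load a dataset manifest (JSON) into assembled records.

    Expected structure::

        {"fasta": "proteins.fasta", "labels": "labels.tsv",
         "proteins": [{"id": "p1", "pssm": "p1.pssm", "ss": "p1.ss"}, ...]}

    Paths are relative to the manifest's directory.  The ``ss`` file may be
    a DSSP output file or a bare one-line 9-state string.
    """
    import json

    path = Path(path)
    base = path.parent
    spec = json.loads(path.read_text())
    seqs = {r.id: r for r in parse_fasta((base / spec["fasta"]).read_text())}
    label_map = parse_labels((base / spec["labels"]).read_text()) if spec.get("labels") else {}
    records = []
    for entry in spec["proteins"]:
        pid = entry["id"]
        if pid not in seqs:
            raise FormatError(f"manifest protein '{pid}' missing from FASTA")
        pssm = parse_pssm((base / entry["pssm"]).read_text()) if entry.get("pssm") else None
        ss = None
        if entry.get("ss"):
            ss_text = (base / entry["ss"]).read_text()
            if _DSSP_SENTINEL in ss_text:
                ss = parse_dssp(ss_text)
            else:
                ss = ss_text.strip()
        records.append(assemble_record(seqs[pid], pssm=pssm, ss9=ss, labels=label_map.get(pid)))
    return records
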