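"""FASTA and TSV readers/writers for sites, energy matrices and motifs."""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy_models import BASES, EnergyMatrix
from .motif_discovery import MotifModel

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA; upcases mixed-case input with a warning, rejects non-ACGT."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning("record %s: lowercase bases upcased", rec.id)
            seq = seq.upper()
        bad = set(seq) - set(BASES)
        if bad:
            raise FormatError(
                f"record {rec.id}: non-ACGT characters {sorted(bad)}"
            )
        if rec.id in seen:
            logger.warning("duplicate FASTA id %s", rec.id)
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def sample_fasta_records(sample) -> list[tuple[str, str]]:
    width = len(str(sample.n))
    return [
        (f"{sample.model_id}_site{i:0{max(3, width)}d}", s)
        for i, s in enumerate(sample.sites, start=1)
    ]


# -- energy matrix / motif TSV dialect --------------------------------------
#
# '#'-prefixed "key: value" comments carry model_id and mu (plus mode and
# effective_n for motif count matrices), then a "pos\tA\tC\tG\tT" header
# and one row per position, 1-based.

_HEADER = ["pos"] + list(BASES)


def write_matrix_tsv(matrix: EnergyMatrix, path) -> None:
    lines = [
        f"# model_id: {matrix.model_id}",
        f"# mu: {matrix.mu_default!r}",
        "\t".join(_HEADER),
    ]
    for j in range(matrix.width):
        vals = "\t".join(f"{float(v)!r}" for v in matrix.energies[j])
        lines.append(f"{j + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_table(path) -> tuple[dict, list[list[str]]]:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"{path}: no table rows found")
    return meta, rows


def _read_positions_table(path) -> tuple[dict, np.ndarray]:
    meta, rows = _parse_table(path)
    header = [h.strip() for h in rows[0]]
    for col in _HEADER:
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    idx = {col: header.index(col) for col in _HEADER}
    values = []
    for r, fields in enumerate(rows[1:], start=1):
        try:
            pos = int(fields[idx["pos"]])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: bad position in row {r}") from None
        if pos != r:
            raise FormatError(
                f"{path}: positions must be 1..L in order; row {r} has {pos}"
            )
        values.append([float(fields[idx[b]]) for b in BASES])
    return meta, np.array(values)


def read_matrix_tsv(path) -> EnergyMatrix:
    meta, values = _read_positions_table(path)
    undet = frozenset(
        (j + 1, BASES[b])
        for j in range(values.shape[0])
        for b in range(4)
        if np.isnan(values[j, b])
    )
    return EnergyMatrix(
        meta.get("model_id", Path(path).stem),
        values,
        float(meta.get("mu", -0.5)),
        undet,
    )


def write_motif_tsv(model: MotifModel, path) -> None:
    lines = [
        f"# mode: {model.mode}",
        f"# effective_n: {model.effective_n}",
        "\t".join(_HEADER),
    ]
    for j in range(model.width):
        vals = "\t".join(f"{float(v)!r}" for v in model.counts[j])
        lines.append(f"{j + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motif_tsv(path) -> MotifModel:
    meta, counts = _read_positions_table(path)
    mode = meta.get("mode", "fixed")
    eff = int(meta.get("effective_n", int(round(counts[0].sum()))))
    return MotifModel(mode, counts, (), eff)
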