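"""Readers and report writers: FASTA / plain-text input, TSV + JSON output."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .parsing import DNA_ALPHABET, SymbolSequence
from .randomness import PermutationSummary, RateReport

logger = logging.getLogger("mdlseq")

RATE_COLUMNS = [
    "model", "n", "m", "entropy", "first_term", "rest_terms",
    "total_bits", "rate", "minimum",
]


def read_fasta(
    path,
    alphabet: frozenset[str] = DNA_ALPHABET,
    concatenate: bool = False,
) -> SymbolSequence:
    """Read a FASTA file into a validated SymbolSequence.

    By default only the first record is used; ``concatenate=True`` joins
    all records.  Symbols are uppercased, and anything outside the declared
    alphabet (including N) raises with its position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if concatenate:
        raw = "".join(str(r.seq) for r in records)
        ident = "+".join(r.id for r in records)
    else:
        raw = str(records[0].seq)
        ident = records[0].id
    logger.info("read FASTA record %s: %d symbols", ident, len(raw))
    return SymbolSequence(raw, alphabet)


def read_plain_text(path, alphabet: frozenset[str]) -> SymbolSequence:
    """Read a bare symbol string (whitespace stripped) from a text file."""
    raw = "".join(Path(path).read_text().split())
    return SymbolSequence(raw, alphabet)


def rate_reports_to_rows(reports: list[RateReport]) -> list[dict]:
    return [
        {
            "model": r.label,
            "n": r.n,
            "m": r.m,
            "entropy": r.entropy_per_word,
            "first_term": r.entropy_bits,
            "rest_terms": r.complexity_bits,
            "total_bits": r.total_bits,
            "rate": r.rate,
            "minimum": r.minimum,
        }
        for r in reports
    ]


def write_rate_table(reports: list[RateReport], tsv_path, json_path=None) -> None:
    """Write a scan as TSV (floats at 4 decimals) plus optional full-precision
    JSON companion."""
    rows = rate_reports_to_rows(reports)
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(RATE_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c])
                    for c in RATE_COLUMNS
                )
                + "\n"
            )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1))


def write_permutation_table(
    summary: PermutationSummary, tsv_path, json_path=None
) -> None:
    """Write permutation statistics as method x statistic x model TSV."""
    methods = list(summary.stats)
    labels = sorted(next(iter(summary.stats.values())))
    with open(tsv_path, "w") as fh:
        fh.write("method\tstatistic\t" + "\t".join(labels) + "\n")
        for meth in methods:
            for stat in ("mean", "sd", "q01", "q99"):
                vals = [getattr(summary.stats[meth][lab], stat) for lab in labels]
                fh.write(
                    f"{meth}\t{stat}\t" + "\t".join(f"{v:.4f}" for v in vals) + "\n"
                )
    if json_path is not None:
        payload = {
            "replicates": summary.replicates,
            "seed": summary.seed,
            "stats": {
                meth: {lab: vars(st) for lab, st in per.items()}
                for meth, per in summary.stats.items()
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))
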