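"""Reading and writing haplotype profile tables and reference FASTA.

The variant-table dialect is tab-separated with columns
``sample_id  population  region  range  variants`` where ``range`` is a
comma-separated list of inclusive np intervals (``1-16569`` for the whole
molecule) and ``variants`` is a space-separated list of mutation tokens.
"""

from __future__ import annotations

import csv
import io

from Bio import SeqIO

from mitofounder.variants import (
    Haplotype, Variant, WHOLE_RANGE, parse_profile, render_profile,
)

COLUMNS = ["sample_id", "population", "region", "range", "variants"]


def _parse_range(text: str):
    text = text.strip()
    if not text or text.lower() in ("whole", "full"):
        return WHOLE_RANGE
    return tuple(tuple(int(x) for x in part.split("-"))
                 for part in text.split(","))


def _render_range(rng) -> str:
    return ",".join(f"{a}-{b}" for a, b in rng)


def read_profiles(file, reference: str = "rCRS") -> list[Haplotype]:
    """Read a TSV variant table into haplotypes."""
    close = False
    if not hasattr(file, "read"):
        file = open(file, newline="")
        close = True
    try:
        reader = csv.DictReader(file, delimiter="\t")
        missing = set(COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"profile table missing columns: {sorted(missing)}")
        out = []
        for row in reader:
            out.append(Haplotype(
                sample_id=row["sample_id"],
                population=row["population"],
                region=row["region"] or "unassigned",
                variants=parse_profile(row["variants"] or ""),
                reference=reference,
                range=_parse_range(row["range"]),
            ))
        return out
    finally:
        if close:
            file.close()


def write_profiles(haplotypes, file) -> None:
    """Write haplotypes as a normalized TSV variant table."""
    close = False
    if not hasattr(file, "write"):
        file = open(file, "w", newline="")
        close = True
    try:
        writer = csv.writer(file, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for h in haplotypes:
            writer.writerow([h.sample_id, h.population, h.region,
                             _render_range(h.range),
                             render_profile(h.variants)])
    finally:
        if close:
            file.close()


def read_reference_fasta(file) -> str:
    """Read a single-record reference FASTA into an uppercase string."""
    records = list(SeqIO.parse(file, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def read_diff_table(file) -> frozenset[Variant]:
    """Read a reference-difference list (one variant token per line,
    '#' comments allowed)."""
    close = False
    if not hasattr(file, "read"):
        file = open(file)
        close = True
    try:
        tokens = []
        for line in file:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
        return parse_profile(" ".join(tokens))
    finally:
        if close:
            file.close()
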