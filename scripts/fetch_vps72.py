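#!/usr/bin/env python
"""Fetch the five VPS72/YL1 ortholog records from NCBI and build an alignment.

Retrieves the protein records for human (NP_005988.1), mouse (NP_033362.2),
Xenopus (NP_001085907.1), fruit fly (NP_001285823.1) and budding yeast
(AHY75432.1), extracts the annotated YL1-C / YL1 C-terminal domain region
(pfam08265) from each GenPept feature table, writes

    data/vps72_orthologs.fasta        unaligned full-length sequences
    data/vps72_yl1c_spans.csv         1-based residue span of YL1-C per record
    data/vps72_orthologs.aln.fasta    MAFFT (Clustal-style) global alignment

and requires network access plus ``mafft`` on PATH.  Run it once, then the
conservation acceptance test can score the alignment.
"""

from __future__ import annotations

import csv
import io
import shutil
import subprocess
import sys
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "human": "NP_005988.1",
    "mouse": "NP_033362.2",
    "xenopus": "NP_001085907.1",
    "fruit_fly": "NP_001285823.1",
    "budding_yeast": "AHY75432.1",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def efetch(acc: str, rettype: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "protein", "id": acc, "rettype": rettype, "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as fh:
        return fh.read().decode()


def yl1c_span(genpept: str) -> tuple[int, int]:
    """1-based inclusive span of the YL1-C region from a GenPept feature table."""
    from Bio import SeqIO

    rec = SeqIO.read(io.StringIO(genpept), "genbank")
    for feat in rec.features:
        if feat.type != "Region":
            continue
        note = " ".join(feat.qualifiers.get("region_name", [])
                        + feat.qualifiers.get("note", []))
        if "YL1" in note or "pfam08265" in note:
            return int(feat.location.start) + 1, int(feat.location.end)
    raise RuntimeError("no YL1-C region annotation found")


def main() -> None:
    if shutil.which("mafft") is None:
        sys.exit("mafft not found on PATH")
    DATA_DIR.mkdir(exist_ok=True)
    fasta_path = DATA_DIR / "vps72_orthologs.fasta"
    spans_path = DATA_DIR / "vps72_yl1c_spans.csv"
    aln_path = DATA_DIR / "vps72_orthologs.aln.fasta"

    records, spans = [], []
    for species, acc in ACCESSIONS.items():
        print(f"fetching {species} ({acc}) ...")
        fasta = efetch(acc, "fasta")
        header, *body = fasta.strip().splitlines()
        records.append(f">{acc}\n" + "\n".join(body))
        start, end = yl1c_span(efetch(acc, "gp"))
        spans.append({"id": acc, "species": species, "start": start, "end": end})

    fasta_path.write_text("\n".join(records) + "\n")
    with open(spans_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "species", "start", "end"])
        writer.writeheader()
        writer.writerows(spans)

    aligned = subprocess.run(
        ["mafft", "--globalpair", "--maxiterate", "1000", str(fasta_path)],
        check=True, capture_output=True, text=True,
    ).stdout
    aln_path.write_text(aligned)
    print(f"wrote {fasta_path}, {spans_path}, {aln_path}")


if __name__ == "__main__":
    main()
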