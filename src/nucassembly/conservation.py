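"""Pairwise percent identity/similarity over a provided protein alignment.

Scores a multiple alignment the way the SIAS service does: over a column
window, count aligned residue pairs that are identical (identity) or that
fall in the same physicochemical class (similarity), and divide by a stated
denominator.  The default denominator is the length of the shorter ungapped
sequence over the region (SIAS's documented default); the alignment-window
and mean-length conventions are selectable.  Building the alignment itself
is delegated to an external aligner (ClustalO/MAFFT); this module only
consumes aligned FASTA.

Residue coordinates in all interfaces are 1-based inclusive (the NCBI
convention used for domain annotations such as the VPS72 YL1-C domain,
pfam08265).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

GAP = "-"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# standard physicochemical classes; every amino acid appears exactly once,
# so same-class contains all identity pairs and identity <= similarity
SIMILARITY_GROUPS: dict[str, tuple[str, ...]] = {
    "default": ("AVLIM", "FYW", "ST", "KRH", "DE", "NQ", "C", "GP"),
}

DENOMINATORS = ("shortest", "alignment", "mean")


@dataclass
class ConservationScore:
    id_a: str
    id_b: str
    region: tuple[int, int]  # column window, 0-based half-open
    identity_percent: float
    similarity_percent: float
    n_identical: int
    n_similar: int
    denominator: int
    denominator_convention: str
    similarity_grouping: str


@dataclass
class AlignmentBlock:
    """Equal-length gapped residue strings keyed by sequence id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows differ in length: {lengths}")
        for sid, s in self.sequences.items():
            bad = set(s.upper()) - AMINO_ACIDS - {GAP, "X"}
            if bad:
                raise ValueError(f"sequence {sid!r}: unexpected symbols {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "AlignmentBlock":
        aln = AlignIO.read(str(path), "fasta")
        return cls({rec.id: str(rec.seq).upper() for rec in aln})

    def ungapped_length(self, sid: str, region: tuple[int, int] | None = None) -> int:
        s = self._row(sid)
        if region is not None:
            s = s[region[0] : region[1]]
        return sum(1 for c in s if c != GAP)

    def _row(self, sid: str) -> str:
        try:
            return self.sequences[sid]
        except KeyError:
            raise KeyError(f"sequence {sid!r} not in alignment ({self.ids})") from None

    def column_of_residue(self, sid: str, residue_index: int) -> int:
        """Alignment column (0-based) of the 1-based ungapped residue index."""
        s = self._row(sid)
        if residue_index < 1:
            raise ValueError("residue indices are 1-based")
        count = 0
        for col, c in enumerate(s):
            if c != GAP:
                count += 1
                if count == residue_index:
                    return col
        raise ValueError(
            f"sequence {sid!r} has only {count} residues; index {residue_index} out of range"
        )


def _group_lookup(grouping: str) -> dict[str, int]:
    groups = SIMILARITY_GROUPS[grouping]
    table: dict[str, int] = {}
    for k, members in enumerate(groups):
        for aa in members:
            table[aa] = k
    return table


def pairwise_scores(
    block: AlignmentBlock,
    pair: tuple[str, str],
    region: tuple[int, int] | None = None,
    convention: str = "shortest",
    grouping: str = "default",
) -> ConservationScore:
    """Percent identity and similarity for one sequence pair.

    ``region`` is a 0-based half-open column window (None = all columns).
    Columns where either sequence is gapped contribute to no numerator;
    the denominator follows ``convention``: ``shortest`` (ungapped length of
    the shorter sequence over the region), ``alignment`` (window width) or
    ``mean`` (mean ungapped length).
    """
    if convention not in DENOMINATORS:
        raise ValueError(f"unknown denominator convention {convention!r}")
    a = block._row(pair[0])
    b = block._row(pair[1])
    region = (0, block.n_columns) if region is None else region
    lo, hi = region
    if not 0 <= lo < hi <= block.n_columns:
        raise ValueError(f"region {region} outside alignment columns (0, {block.n_columns})")

    table = _group_lookup(grouping)
    n_id = n_sim = 0
    for ca, cb in zip(a[lo:hi], b[lo:hi]):
        if ca == GAP or cb == GAP:
            continue
        if ca == cb:
            n_id += 1
            n_sim += 1
        elif table.get(ca) is not None and table.get(ca) == table.get(cb):
            n_sim += 1

    len_a = block.ungapped_length(pair[0], region)
    len_b = block.ungapped_length(pair[1], region)
    if convention == "shortest":
        denom = min(len_a, len_b)
    elif convention == "alignment":
        denom = hi - lo
    else:
        denom = round((len_a + len_b) / 2)
    if denom == 0:
        raise ValueError("empty region: zero-length denominator")

    return ConservationScore(
        id_a=pair[0],
        id_b=pair[1],
        region=(lo, hi),
        identity_percent=100.0 * n_id / denom,
        similarity_percent=100.0 * n_sim / denom,
        n_identical=n_id,
        n_similar=n_sim,
        denominator=denom,
        denominator_convention=convention,
        similarity_grouping=grouping,
    )


def extract_domain(
    block: AlignmentBlock,
    spans: dict[str, tuple[int, int]],
) -> tuple[AlignmentBlock, tuple[int, int]]:
    """Slice the minimal column window covering per-sequence residue spans.

    ``spans`` maps sequence id to a 1-based inclusive ungapped residue span
    (the NCBI domain annotation for that sequence).  Returns the sliced
    block (all rows, alignment preserved) and the column window used.
    """
    if not spans:
        raise ValueError("no spans given")
    cols = []
    for sid, (start, end) in spans.items():
        if start > end:
            raise ValueError(f"span for {sid!r} has start > end")
        cols.append(block.column_of_residue(sid, start))
        cols.append(block.column_of_residue(sid, end))
    lo, hi = min(cols), max(cols) + 1
    return AlignmentBlock({sid: s[lo:hi] for sid, s in block.sequences.items()}), (lo, hi)


def all_pairwise(
    block: AlignmentBlock,
    region: tuple[int, int] | None = None,
    convention: str = "shortest",
    grouping: str = "default",
) -> "list[ConservationScore]":
    """Scores for every unordered id pair of the alignment."""
    ids = block.ids
    return [
        pairwise_scores(block, (ids[i], ids[j]), region, convention, grouping)
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
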