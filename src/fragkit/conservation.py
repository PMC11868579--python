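"""Binding-site vs global ortholog conservation from a multiple sequence alignment.

Given an aligned ortholog family and one or more binding sites expressed as
residue positions on the reference sequence (e.g. the 20 residues closest to
a bound ligand), this module computes per-ortholog percent identity over all
reference-anchored columns (global) and over the site columns alone, so the
two can be compared on a scatter plot. Strict identity is used — no
substitution-matrix similarity.

Counting rule (reference-anchored): columns where the reference is gapped
are never counted; an ortholog gap at a counted column is a mismatch by
default (set ``skip_ortholog_gaps=True`` to drop such columns from the
denominator instead). 'X' matches nothing, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, UndefinedIdentityError

GAP = "-"


@dataclass
class Alignment:
    """An ordered aligned FASTA with a designated reference record."""

    records: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        self.records = [(rid, seq.upper()) for rid, seq in self.records]
        if self.reference_id not in {rid for rid, _ in self.records}:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(record_id)

    @property
    def reference_sequence(self) -> str:
        return self.sequence(self.reference_id)


def read_alignment(path_or_handle, reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA; the first record is the reference by default."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(path_or_handle, "fasta")]
    if not records:
        raise ValueError("no FASTA records found")
    return Alignment(records=records, reference_id=reference_id or records[0][0])


def read_alignment_text(text: str, reference_id: str | None = None) -> Alignment:
    return read_alignment(StringIO(text), reference_id)


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site as 1-based ungapped reference positions.

    ``offset`` maps structure residue numbers to reference positions when the
    crystallised construct is renumbered (e.g. an engineered protein starting
    at L36 of the full-length sequence): reference position = residue number
    + offset.
    """

    name: str
    reference_positions: frozenset[int]

    def __init__(self, name: str, reference_positions: Iterable[int], offset: int = 0):
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self,
            "reference_positions",
            frozenset(int(p) + offset for p in reference_positions),
        )
        if any(p < 1 for p in self.reference_positions):
            raise ValueError(f"site {name!r}: positions must be >= 1 after offset")


def map_reference_positions(alignment: Alignment) -> dict[int, int]:
    """Bijection from 1-based ungapped reference positions to 0-based columns."""
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(alignment.reference_sequence):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    if not mapping:
        raise ValueError("reference sequence is all gaps")
    return mapping


def pairwise_identity(
    alignment: Alignment,
    ortholog_id: str,
    columns: Sequence[int] | None = None,
    skip_ortholog_gaps: bool = False,
) -> float:
    """Percent identity of an ortholog to the reference over selected columns.

    With ``columns`` omitted, all columns where the reference is non-gap are
    counted. Raises :class:`UndefinedIdentityError` when no column is
    countable (never silently 0).
    """
    ref = alignment.reference_sequence
    oth = alignment.sequence(ortholog_id)
    col_pool = range(alignment.length) if columns is None else columns
    matches = 0
    counted = 0
    for col in col_pool:
        r = ref[col]
        if r == GAP:
            continue
        o = oth[col]
        if o == GAP and skip_ortholog_gaps:
            continue
        counted += 1
        if r == o and r != GAP and r != "X" and o != "X":
            matches += 1
    if counted == 0:
        raise UndefinedIdentityError(
            f"no countable columns for {ortholog_id!r} (identity undefined, not 0)"
        )
    return 100.0 * matches / counted


def conservation_profile(
    alignment: Alignment,
    sites: Sequence[SiteDefinition] = (),
    skip_ortholog_gaps: bool = False,
    include_reference: bool = False,
) -> pd.DataFrame:
    """Global and per-site identity for every (non-reference) ortholog.

    Returns a scatter-ready table with one row per ortholog and columns
    ``ortholog_id``, ``global_identity`` and ``<site name>_identity``.
    """
    mapping = map_reference_positions(alignment)
    site_columns: dict[str, list[int]] = {}
    for site in sites:
        cols = []
        for pos in sorted(site.reference_positions):
            if pos not in mapping:
                raise ConfigError(
                    f"site {site.name!r}: reference position {pos} is outside "
                    f"the reference (ungapped length {len(mapping)})"
                )
            cols.append(mapping[pos])
        site_columns[site.name] = cols

    rows = []
    for rid in alignment.ids:
        if rid == alignment.reference_id and not include_reference:
            continue
        row = {
            "ortholog_id": rid,
            "global_identity": pairwise_identity(
                alignment, rid, skip_ortholog_gaps=skip_ortholog_gaps
            ),
        }
        for name, cols in site_columns.items():
            row[f"{name}_identity"] = pairwise_identity(
                alignment, rid, columns=cols, skip_ortholog_gaps=skip_ortholog_gaps
            )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_conservation(
    profile: pd.DataFrame, path, site_names: Sequence[str] | None = None
) -> None:
    """Scatter of site identity (y) against global identity (x), diagonal drawn."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if site_names is None:
        site_names = [
            c[: -len("_identity")]
            for c in profile.columns
            if c.endswith("_identity") and c != "global_identity"
        ]
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in site_names:
        ax.scatter(
            profile["global_identity"],
            profile[f"{name}_identity"],
            s=18,
            alpha=0.8,
            label=name,
        )
    ax.plot([0, 100], [0, 100], ls="--", c="grey", lw=1, label="identity diagonal")
    ax.set_xlabel("global identity (%)")
    ax.set_ylabel("site identity (%)")
    ax.set_xlim(0, 102)
    ax.set_ylim(0, 102)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
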