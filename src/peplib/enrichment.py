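"""Position-wise residue and residue-group enrichment of ranked peptides.

Top-ranked peptides from a screen are profiled position by position: raw
amino-acid frequencies, side-chain-group frequencies under a seven-group
classification (positive R/H/K, negative D/E, polar uncharged S/T/N/Q,
hydrophobic A/V/I/L/M/F/Y/W, and the single-residue groups Cys, Gly, Pro),
group-size-normalized frequencies (each group's frequency divided by its
member count, then rescaled to sum 1 per position, removing composition
bias), per-position pooling of rare residues into a "rest" key, descriptor
comparison against the parent library, and ordered-subsequence motif
containment.  Frequencies are fractions internally; render as percentages at
presentation time.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from .library import CANONICAL_ALPHABET

DEFAULT_GROUPS: dict[str, str] = {
    "positive": "RHK",
    "negative": "DE",
    "polar_uncharged": "STNQ",
    "hydrophobic": "AVILMFYW",
    "cysteine": "C",
    "glycine": "G",
    "proline": "P",
}


@dataclass
class ResidueGroupScheme:
    """A named partition of the 20-letter alphabet into side-chain groups."""

    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self):
        letters = "".join(self.groups.values())
        if sorted(letters) != sorted(CANONICAL_ALPHABET):
            raise ValueError(
                "groups must partition the 20-letter alphabet exactly; got "
                f"{''.join(sorted(letters))!r}"
            )
        self.residue_to_group = {
            ch: name for name, members in self.groups.items() for ch in members
        }

    def group_size(self, name: str) -> int:
        return len(self.groups[name])


def _check_sequences(sequences: Sequence[str]) -> int:
    if not sequences:
        raise ValueError("empty sequence list")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")
    return lengths.pop()


@dataclass
class PositionalFrequencyTable:
    """Long-format position x key frequency table over ``n`` peptides.

    ``table`` has columns ``position`` (1-based), ``key`` (residue, group name
    or ``"rest"``), ``frequency`` and optionally ``normalized``.  Raw
    frequencies sum to 1 within each position.
    """

    table: pd.DataFrame
    n: int

    def at(self, position: int, key: str, column: str = "frequency") -> float:
        sel = self.table[
            (self.table.position == position) & (self.table.key == key)
        ]
        return float(sel[column].iloc[0]) if len(sel) else 0.0

    def position_sum(self, position: int, column: str = "frequency") -> float:
        return float(
            self.table.loc[self.table.position == position, column].sum()
        )


def group_frequencies(
    sequences: Sequence[str], scheme: ResidueGroupScheme | None = None
) -> PositionalFrequencyTable:
    """Per-position frequency of each residue group among ``sequences``."""
    scheme = scheme or ResidueGroupScheme()
    length = _check_sequences(sequences)
    n = len(sequences)
    rows = []
    for p in range(1, length + 1):
        counts = {name: 0 for name in scheme.groups}
        for s in sequences:
            counts[scheme.residue_to_group[s[p - 1]]] += 1
        for name in scheme.groups:
            rows.append(
                {"position": p, "key": name, "frequency": counts[name] / n}
            )
    return PositionalFrequencyTable(pd.DataFrame(rows), n=n)


def normalize_by_group_size(
    table: PositionalFrequencyTable, scheme: ResidueGroupScheme | None = None
) -> PositionalFrequencyTable:
    """Divide each group's frequency by its member count, rescale to sum 1.

    Removes the bias of unequal group sizes: a complete combinatorial library,
    where each group's raw frequency is ``|group|/20``, normalizes to the
    uniform distribution over groups.
    """
    scheme = scheme or ResidueGroupScheme()
    df = table.table.copy()
    df["normalized"] = [
        row.frequency / scheme.group_size(row.key) for row in df.itertuples()
    ]
    for p, sub in df.groupby("position"):
        total = sub["normalized"].sum()
        if total > 0:
            df.loc[sub.index, "normalized"] = sub["normalized"] / total
    return PositionalFrequencyTable(df, n=table.n)


def residue_frequencies_with_rest(
    sequences: Sequence[str], min_count: int = 2
) -> PositionalFrequencyTable:
    """Per-position residue frequencies, pooling rare residues into ``"rest"``.

    A residue occurring in fewer than ``min_count`` peptides at a position is
    pooled into the ``rest`` key there; pooling conserves the total frequency
    mass.  ``min_count=1`` disables pooling.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    length = _check_sequences(sequences)
    n = len(sequences)
    rows = []
    for p in range(1, length + 1):
        counts: dict[str, int] = {}
        for s in sequences:
            counts[s[p - 1]] = counts.get(s[p - 1], 0) + 1
        rest = sum(c for c in counts.values() if c < min_count)
        for ch in sorted(counts):
            if counts[ch] >= min_count:
                rows.append(
                    {"position": p, "key": ch, "frequency": counts[ch] / n}
                )
        if rest:
            rows.append({"position": p, "key": "rest", "frequency": rest / n})
    return PositionalFrequencyTable(pd.DataFrame(rows), n=n)


def descriptor_comparison(
    library_summary: dict | pd.DataFrame,
    top_records: pd.DataFrame,
    top10_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compare descriptor means/sds: whole library vs top-N (vs top-10).

    ``library_summary`` is either a :func:`peplib.properties.library_profile`
    dict or a raw descriptor DataFrame; ``top_records``/``top10_records`` are
    descriptor DataFrames for the selected peptides.  Differences are reported
    as plain mean shifts; no significance testing is performed.
    """
    def _stats(source, name):
        if isinstance(source, dict):
            d = source["descriptors"][name]
            return d["mean"], d["sd"]
        return float(source[name].mean()), float(source[name].std(ddof=1))

    if isinstance(library_summary, dict):
        names = list(library_summary["descriptors"])
    else:
        names = [c for c in library_summary.columns
                 if pd.api.types.is_numeric_dtype(library_summary[c])]
    rows = []
    for name in names:
        if name not in top_records.columns:
            continue
        lib_mean, lib_sd = _stats(library_summary, name)
        top_mean, top_sd = _stats(top_records, name)
        row = {
            "descriptor": name,
            "library_mean": lib_mean, "library_sd": lib_sd,
            "top_mean": top_mean, "top_sd": top_sd,
            "top_diff": top_mean - lib_mean,
        }
        if top10_records is not None:
            t10_mean, t10_sd = _stats(top10_records, name)
            row.update(top10_mean=t10_mean, top10_sd=t10_sd,
                       top10_diff=t10_mean - lib_mean)
        rows.append(row)
    return pd.DataFrame(rows)


def motif_containment(query: str, reference: str) -> tuple[int, ...] | None:
    """Leftmost ordered-subsequence match of ``query`` inside ``reference``.

    Returns the 1-based reference positions of each query letter in the
    leftmost increasing mapping, or None when ``query`` is not an ordered
    subsequence of ``reference``.  E.g. GSVW maps into GSYWYQVWF at positions
    (1, 2, 7, 8).
    """
    if not query:
        raise ValueError("empty query motif")
    positions = []
    start = 0
    for ch in query:
        idx = reference.find(ch, start)
        if idx < 0:
            return None
        positions.append(idx + 1)
        start = idx + 1
    return tuple(positions)
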