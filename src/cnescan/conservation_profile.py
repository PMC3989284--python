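"""Per-column conservation statistics, consensus calling, and segmentation of
absolutely conserved columns into discrete clusters.

Conventions:

* Information content per column is R = 2 - H, with H the Shannon entropy in
  bits of the base frequencies among non-gap residues. An all-identical
  column scores 2 bits; a uniform column scores 0. No small-sample correction
  is applied (family sizes near 38 make it minor), so logo heights are
  reproducible. A display-scaled value (R times the non-gap coverage
  fraction) is carried alongside.
* Consensus characters: '.' where the majority of rows are gapped; uppercase
  modal base where the modal frequency reaches the upper threshold (default
  1.0, i.e. complete conservation); lowercase where it reaches the lower
  threshold (default 0.5); otherwise 'n'. A tie between two modal bases at
  the threshold yields 'n'.
* "Absolutely conserved" means modal frequency exactly 1.0 over non-gap
  residues AND zero gaps in the column (configurable via allow_gaps).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .core_types_io import Alignment

__all__ = [
    "ColumnProfile",
    "ConsensusProfile",
    "ConservedCluster",
    "column_profiles",
    "consensus_string",
    "segment_clusters",
    "cluster_spacings",
    "at_fraction_of_conserved",
]

_BASES = "ACGT"


@dataclasses.dataclass
class ColumnProfile:
    """Statistics for one alignment column."""

    counts: dict[str, int]          # A/C/G/T counts (N excluded)
    n_count: int                    # ambiguous residues
    gap_count: int
    coverage: float                 # non-gap fraction of rows
    modal_base: str                 # '' when no non-gap residues
    modal_freq: float               # over non-gap, non-N residues
    modal_tied: bool                # two or more bases share the modal count
    ic: float                       # 2 - H, bits, over non-gap frequencies
    ic_display: float               # ic scaled by coverage (logo height)


@dataclasses.dataclass
class ConsensusProfile:
    """Column-wise profile of an alignment plus derived consensus helpers."""

    n_records: int
    columns: list[ColumnProfile]

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    def absolutely_conserved(self, allow_gaps: bool = False) -> list[int]:
        """Column indices with modal frequency exactly 1.0; by default also
        require a gap-free column."""
        out = []
        for j, col in enumerate(self.columns):
            if col.modal_base and col.modal_freq == 1.0 and col.n_count == 0:
                if allow_gaps or col.gap_count == 0:
                    out.append(j)
        return out

    def to_dataframe(self, consensus: str | None = None) -> pd.DataFrame:
        rows = []
        for j, c in enumerate(self.columns):
            rows.append({
                "column": j + 1,
                "A": c.counts["A"], "C": c.counts["C"],
                "G": c.counts["G"], "T": c.counts["T"],
                "N": c.n_count, "gap": c.gap_count,
                "coverage": round(c.coverage, 4),
                "modal_base": c.modal_base,
                "modal_freq": round(c.modal_freq, 4),
                "ic_bits": round(c.ic, 4),
                "ic_display": round(c.ic_display, 4),
            })
        df = pd.DataFrame(rows)
        if consensus is not None:
            df["consensus"] = list(consensus)
        return df


@dataclasses.dataclass
class ConservedCluster:
    """A maximal run of absolutely conserved columns (Fig-2A-style box)."""

    label: str                       # c1, c2, ... left to right
    start_col: int                   # 0-based first consensus column
    end_col: int                     # 0-based last consensus column (inclusive)
    conserved_columns: list[int]     # 0-based indices inside the span
    category: str = "other"          # dyad-arm / TAT-containing / other

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_columns)

    @property
    def span(self) -> tuple[int, int]:
        return self.start_col, self.end_col


def column_profiles(aln: Alignment) -> ConsensusProfile:
    """Compute per-column counts, coverage, modal base/frequency and IC."""
    cols = []
    n = aln.n_records
    for j in range(aln.n_cols):
        column = aln.column(j)
        counts = {b: column.count(b) for b in _BASES}
        n_count = column.count("N")
        gap_count = column.count("-")
        non_gap = n - gap_count
        coverage = non_gap / n
        acgt_total = sum(counts.values())
        if acgt_total == 0:
            modal_base, modal_freq, tied = "", 0.0, False
            ic = 0.0
        else:
            best = max(counts.values())
            modal_bases = [b for b in _BASES if counts[b] == best]
            modal_base = modal_bases[0]
            tied = len(modal_bases) > 1
            modal_freq = best / acgt_total
            h = 0.0
            for b in _BASES:
                p = counts[b] / acgt_total
                if p > 0:
                    h -= p * math.log2(p)
            ic = 2.0 - h
        cols.append(ColumnProfile(
            counts=counts, n_count=n_count, gap_count=gap_count,
            coverage=coverage, modal_base=modal_base, modal_freq=modal_freq,
            modal_tied=tied, ic=ic, ic_display=ic * coverage,
        ))
    return ConsensusProfile(n_records=n, columns=cols)


def consensus_string(profile: ConsensusProfile,
                     upper_threshold: float = 1.0,
                     lower_threshold: float = 0.5,
                     gap_threshold: float = 0.5) -> str:
    """Render the consensus: '.' for majority-gap columns, uppercase for
    complete conservation, lowercase for >= lower_threshold, else 'n'."""
    if not (0 < lower_threshold <= upper_threshold <= 1):
        raise ValueError("need 0 < lower_threshold <= upper_threshold <= 1")
    if not (0 < gap_threshold <= 1):
        raise ValueError("gap_threshold must lie in (0, 1]")
    out = []
    for col in profile.columns:
        gap_frac = col.gap_count / profile.n_records
        if gap_frac > gap_threshold or not col.modal_base:
            out.append(".")
        elif col.modal_freq >= upper_threshold and not col.modal_tied:
            out.append(col.modal_base.upper())
        elif col.modal_freq >= lower_threshold and not col.modal_tied:
            out.append(col.modal_base.lower())
        else:
            out.append("n")
    return "".join(out)


def segment_clusters(profile: ConsensusProfile,
                     max_intervening: int = 2,
                     min_conserved: int = 3,
                     allow_gaps: bool = False) -> list[ConservedCluster]:
    """Group absolutely conserved columns into discrete clusters.

    Consecutive conserved columns separated by <= max_intervening
    non-conserved columns belong to the same cluster; clusters with fewer
    than min_conserved conserved columns are dropped; survivors are labelled
    c1, c2, ... left to right. Category assignment: a cluster whose consensus
    contains the TAT triplet is 'TAT-containing' (dyad-arm tagging is done by
    the architecture builder, which knows where the dyads sit).
    """
    conserved = profile.absolutely_conserved(allow_gaps=allow_gaps)
    if not conserved:
        return []
    runs: list[list[int]] = [[conserved[0]]]
    for c in conserved[1:]:
        if c - runs[-1][-1] - 1 <= max_intervening:
            runs[-1].append(c)
        else:
            runs.append([c])
    clusters = []
    for run in runs:
        if len(run) < min_conserved:
            continue
        clusters.append(ConservedCluster(
            label=f"c{len(clusters) + 1}",
            start_col=run[0], end_col=run[-1],
            conserved_columns=run,
        ))
    # TAT tagging on the conserved consensus text of each cluster
    for cl in clusters:
        text = "".join(
            profile.columns[j].modal_base for j in
            range(cl.start_col, cl.end_col + 1)
        )
        if "TAT" in text:
            cl.category = "TAT-containing"
    return clusters


def cluster_spacings(clusters: list[ConservedCluster],
                     per_sequence: Alignment) -> pd.DataFrame:
    """Ungapped distances between consecutive clusters, per family member.

    For each sequence and each adjacent cluster pair, the distance is the
    number of that sequence's residues strictly between the end of one
    cluster span and the start of the next. A cluster span fully deleted in
    a sequence yields a missing value for its two flanking gaps.
    """
    if len(clusters) < 2:
        raise ValueError("cluster_spacings needs at least 2 clusters")
    rows = []
    for rid, gapped in per_sequence.records:
        for a, b in zip(clusters, clusters[1:]):
            left_present = any(gapped[j] != "-" for j in a.conserved_columns)
            right_present = any(gapped[j] != "-" for j in b.conserved_columns)
            if not (left_present and right_present):
                dist = np.nan
            else:
                between = gapped[a.end_col + 1: b.start_col]
                dist = float(sum(1 for c in between if c != "-"))
            rows.append({
                "seq_id": rid,
                "pair": f"{a.label}-{b.label}",
                "distance": dist,
            })
    return pd.DataFrame(rows)


def spacing_summary(spacings: pd.DataFrame) -> pd.DataFrame:
    """Min/max/width of observed spacings per adjacent cluster pair."""
    g = spacings.dropna().groupby("pair", sort=False)["distance"]
    out = g.agg(["min", "max"]).reset_index()
    out["width"] = out["max"] - out["min"]
    return out


def plot_ic_profile(profile: ConsensusProfile, path: "str",
                    consensus: "str | None" = None) -> None:
    """Write a simple conservation plot: per-column information content
    (coverage-scaled) as bars, coloured by modal base, consensus lettering
    along the x axis. A lightweight logo substitute for quick inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839",
              "": "#999999"}
    heights = [c.ic_display for c in profile.columns]
    bar_colors = [colors.get(c.modal_base, "#999999") for c in profile.columns]
    fig, ax = plt.subplots(figsize=(max(6, profile.n_cols / 12), 2.5))
    ax.bar(range(1, profile.n_cols + 1), heights, color=bar_colors, width=1.0)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("alignment column")
    if consensus is not None:
        ax.set_title(consensus, fontsize=6, family="monospace")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def at_fraction_of_conserved(profile: ConsensusProfile,
                             allow_gaps: bool = False) -> float:
    """Percent of absolutely conserved columns whose base is A or T.

    Returns NaN when there are no absolutely conserved columns.
    """
    cols = profile.absolutely_conserved(allow_gaps=allow_gaps)
    if not cols:
        return float("nan")
    at = sum(1 for j in cols if profile.columns[j].modal_base in "AT")
    return 100.0 * at / len(cols)
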