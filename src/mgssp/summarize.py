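"""Derived analytics over substitution profiles.

Average per-amino-acid substitution matrices, rarity distributions,
stratification of lineages by somatic hypermutation load, and sequence-logo
export (letter height = m * f, so the stack height at a position equals its
substitution frequency m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mgssp.profile import (
    AA_INDEX,
    AA_ORDER,
    GSSP,
    RarityTable,
    align_to_germline,
    build_gssp,
)

logger = logging.getLogger(__name__)

#: Physicochemical colour groups used in logo plots:
#: basic (blue), acidic (red), polar/small (green), hydrophobic (black),
#: amide (purple).
LOGO_COLOR_GROUPS = {
    **dict.fromkeys("RKH", "blue"),
    **dict.fromkeys("DE", "red"),
    **dict.fromkeys("GSTYC", "green"),
    **dict.fromkeys("PAWFLIMV", "black"),
    **dict.fromkeys("NQ", "purple"),
}


@dataclass
class AvgSubstitutionMatrix:
    """20x20 average substitution-bias matrix over qualifying positions.

    Row g holds the mean normalized substitution frequency from germline
    residue g to each other residue; rows with no qualifying position are
    NaN (undefined), never silently zero. ``row_counts`` gives the number
    of qualifying positions behind each row.
    """

    matrix: np.ndarray
    row_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AA_ORDER), columns=list(AA_ORDER))


def average_substitution_matrix(
    profiles: list[GSSP], min_m: float = 0.05
) -> AvgSubstitutionMatrix:
    """Average substitution bias per germline amino acid across profiles.

    Positions mutated in fewer than ``min_m`` of lineages are excluded
    (undersampled bias), as are positions whose germline residue differs
    between alleles (polymorphism). Each remaining position's bias vector
    is normalized to 1 and vectors are averaged within each germline
    residue group.
    """
    sums = np.zeros((20, 20))
    counts = np.zeros(20, dtype=int)
    for gssp in profiles:
        for prof in gssp.positions:
            if prof.m < min_m or prof.n_mutated == 0:
                continue
            if len(prof.germline_residues) != 1:
                continue
            (germ,) = prof.germline_residues
            if germ not in AA_INDEX:
                continue
            f = prof.f
            total = f.sum()
            if total <= 0:
                continue
            sums[AA_INDEX[germ]] += f / total
            counts[AA_INDEX[germ]] += 1
    matrix = np.full((20, 20), np.nan)
    defined = counts > 0
    matrix[defined] = sums[defined] / counts[defined, None]
    for i in np.flatnonzero(~defined):
        logger.info("average substitution matrix: row %s undefined", AA_ORDER[i])
    return AvgSubstitutionMatrix(matrix=matrix, row_counts=counts)


DEFAULT_RARITY_EDGES = (0.0, 0.25, 0.5, 0.75, 0.975, 0.995, 1.0)


def rarity_histogram(
    table: RarityTable, edges: tuple[float, ...] = DEFAULT_RARITY_EDGES
) -> pd.DataFrame:
    """Histogram of rarity over all defined (possible) substitutions.

    Also reports the fraction of possible substitutions never observed
    (rarity exactly 1.0). Returned frame has one row per bin plus the
    attrs 'n_entries' and 'fraction_unobserved'.
    """
    values = np.asarray(list(table.entries.values()), dtype=float)
    if values.size == 0:
        raise ValueError("empty rarity table")
    counts, _ = np.histogram(values, bins=np.asarray(edges))
    out = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "fraction": counts / values.size,
        }
    )
    out.attrs["n_entries"] = int(values.size)
    out.attrs["fraction_unobserved"] = float(np.mean(values == 1.0))
    return out


def stratify_by_shm(
    representatives: list[str],
    gene,
    low_max: int = 8,
    high_min: int = 21,
) -> dict:
    """Split lineage representatives into low- and high-SHM strata.

    A representative's SHM load is its count of non-germline residues
    after alignment to the gene. Low: at most ``low_max`` substitutions;
    high: at least ``high_min`` (counts in between belong to neither).
    Builds a profile per non-empty stratum (lineage-count floor waived) and
    inventories substitutions observed in only one stratum.
    """
    residues = gene.germline_residues
    strata: dict[str, list[str]] = {"low": [], "high": []}
    inventories: dict[str, set] = {"low": set(), "high": set()}
    for rep in representatives:
        observed = align_to_germline(rep, gene)
        if observed is None:
            continue
        subs = {
            (pos, aa)
            for pos, aa in observed.items()
            if aa not in residues.get(pos, frozenset())
        }
        if len(subs) <= low_max:
            stratum = "low"
        elif len(subs) >= high_min:
            stratum = "high"
        else:
            continue
        strata[stratum].append(rep)
        inventories[stratum] |= subs
    result: dict = {
        "low_n": len(strata["low"]),
        "high_n": len(strata["high"]),
        "unique_to_low": inventories["low"] - inventories["high"],
        "unique_to_high": inventories["high"] - inventories["low"],
        "shared": inventories["low"] & inventories["high"],
    }
    for name in ("low", "high"):
        if strata[name]:
            result[f"{name}_gssp"] = build_gssp(
                strata[name], gene, min_count=1, warn_below=0
            )
        else:
            logger.info("stratify_by_shm: %s stratum empty", name)
            result[f"{name}_gssp"] = None
    return result


def logo_export(gssp: GSSP, coloring: dict[str, str] | None = None) -> pd.DataFrame:
    """Numeric logo specification: one row per (position, residue) letter.

    Letter height is m * f, so heights at a position stack to m. Germline
    residues are annotated per position for display beneath the stack.
    """
    if coloring is None:
        coloring = LOGO_COLOR_GROUPS
    rows = []
    for prof in gssp.positions:
        f = prof.f
        germline = ",".join(sorted(prof.germline_residues))
        for aa in AA_ORDER:
            h = prof.m * f[AA_INDEX[aa]]
            if h > 0:
                rows.append(
                    {
                        "position": prof.position,
                        "residue": aa,
                        "height": h,
                        "color_group": coloring.get(aa, "black"),
                        "germline": germline,
                    }
                )
    return pd.DataFrame(rows, columns=["position", "residue", "height", "color_group", "germline"])


def plot_logo(gssp: GSSP, path=None, ax=None):
    """Render the logo specification as stacked letters (matplotlib).

    Thin layer over :func:`logo_export`; the numeric specification is the
    contract, the rendering is for human eyes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = logo_export(gssp)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(gssp.positions) / 6), 3))
    for position, group in spec.groupby("position"):
        bottom = 0.0
        for row in group.sort_values("height", ascending=True).itertuples():
            ax.text(
                row.position,
                bottom + row.height / 2,
                row.residue,
                ha="center",
                va="center",
                fontsize=6 + 14 * min(row.height, 1.0),
                color=row.color_group,
                fontweight="bold",
            )
            bottom += row.height
    positions = [p.position for p in gssp.positions]
    ax.set_xlim(min(positions) - 1, max(positions) + 1)
    ax.set_ylim(0, max(0.05, spec.groupby("position")["height"].sum().max() * 1.1) if len(spec) else 1)
    ax.set_xlabel(f"position ({gssp.numbering_dialect})")
    ax.set_ylabel("substitution frequency")
    ax.set_title(f"{gssp.gene} (n={gssp.n_lineages} lineages)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
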