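"""Part 2: normalization, mode imputation, selectivity ranking.

Each screen's raw peptide counts are first divided by the screen's total read
count (sequencing-depth normalization), then by the depth-normalized frequency
of the same peptide in the reference library — an amplified but unselected
aliquot sequenced alongside the screens. The reference division cancels the
library's skewed naive distribution and the amplification advantage of
parasitic clones, which inflate *every* screen including the reference.

A peptide absent from a screen cannot be given frequency zero (the later ratio
would divide by zero), so absences are imputed with the screen's *non-zero
mode*: the most common strictly positive normalized frequency, which in deep
screens is the value shared by the mass of singleton reads. The selectivity
ratio — mean normalized frequency across positive screens over mean across
negative screens — is the sort key of the comparison matrix; peptides high in
every positive screen and low in every negative screen distil to the top rows.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .extract import ScreenTable
from .scheme import SelPepError

logger = logging.getLogger(__name__)

_RATIO_COL = "ratio"
_FLOAT_FMT = "%.12g"


class EmptyScreenError(SelPepError, ValueError):
    """A screen with zero reads cannot be normalized."""


class ConfigurationError(SelPepError, ValueError):
    """Role assignment or run configuration is inconsistent."""


@dataclass(frozen=True)
class RoleAssignment:
    """Which screen is the reference, and which are positives / negatives."""

    reference: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(self.positives))
        object.__setattr__(self, "negatives", tuple(self.negatives))
        groups = [self.reference, *self.positives, *self.negatives]
        if len(set(groups)) != len(groups):
            raise ConfigurationError(f"screen roles overlap: {groups}")
        if not self.positives:
            raise ConfigurationError("at least one positive screen is required")

    @property
    def screens(self) -> tuple[str, ...]:
        return (self.reference, *self.positives, *self.negatives)


@dataclass
class NormalizedScreen:
    """Fully normalized frequencies for one screen (present peptides only)."""

    screen_id: str
    values: dict[str, float]
    total_reads_used: int
    nonzero_mode: float


@dataclass
class SelectivityMatrix:
    """Union-of-peptides x screens comparison matrix, sorted by selectivity.

    ``data`` holds one row per peptide and one column per screen (reference
    first, then positives, then negatives); ``imputed`` marks the cells filled
    with a screen's non-zero mode rather than observed; ``ratio`` is the sort
    key (mean positive / mean negative, or the min-across-screens score in
    ubiquitous mode); ``positives_observed`` counts non-imputed positive cells
    per row — the paper-style "high in at least m of n positives" check is a
    visual one, so the count is reported rather than filtered on.
    """

    data: pd.DataFrame
    imputed: pd.DataFrame
    ratio: pd.Series
    pos_mean: pd.Series
    positives_observed: pd.Series
    assignment: RoleAssignment
    ubiquitous: bool = False

    @property
    def peptides(self) -> list[str]:
        return list(self.data.index)


def depth_normalize(table: ScreenTable) -> dict[str, float]:
    """Counts divided by the screen's total read count (frequency per read)."""
    total = table.stats.total_reads
    if total <= 0:
        raise EmptyScreenError(f"screen {table.screen_id}: total_reads is 0")
    return {p: c / total for p, c in table.counts.items() if c > 0}


def nonzero_mode(values) -> float:
    """Most frequent strictly positive value; ties broken by the smallest value.

    This is the imputation value for peptides absent from a screen: in real
    screens it is the normalized frequency shared by the bulk of singletons,
    i.e. the best guess for "present below detection".
    """
    positive = [v for v in values if v > 0]
    if not positive:
        raise ValueError("nonzero_mode needs at least one strictly positive value")
    tally = Counter(positive)
    best_count = max(tally.values())
    return min(v for v, n in tally.items() if n == best_count)


def reference_normalize(
    screen_id: str,
    screen_depthnorm: dict[str, float],
    reference_depthnorm: dict[str, float],
    reference_mode: float,
    *,
    total_reads_used: int = 0,
) -> NormalizedScreen:
    """Divide a screen's depth-normalized frequencies by the reference's.

    Peptides absent from the reference fall back to the reference's non-zero
    mode as denominator — the same imputation rule the screens use, extended to
    the reference column so that novel selected clones (never seen in the naive
    pool) still receive a finite, large normalized value.
    """
    if reference_mode <= 0:
        raise ValueError(f"reference_mode must be > 0, got {reference_mode}")
    values = {
        p: v / reference_depthnorm.get(p, reference_mode)
        for p, v in screen_depthnorm.items()
    }
    return NormalizedScreen(
        screen_id=screen_id,
        values=values,
        total_reads_used=total_reads_used,
        nonzero_mode=nonzero_mode(values.values()) if values else float("nan"),
    )


def normalize_screens(
    tables: dict[str, ScreenTable], assignment: RoleAssignment
) -> dict[str, NormalizedScreen]:
    """Depth- and reference-normalize every screen of an assignment.

    The reference screen itself is carried at depth-normalized level (dividing
    it by itself would be identically one); its entry supplies the reference
    column of the comparison matrix.
    """
    missing = [s for s in assignment.screens if s not in tables]
    if missing:
        raise ConfigurationError(f"missing screen tables: {missing}")
    ref_table = tables[assignment.reference]
    ref_dn = depth_normalize(ref_table)
    if not ref_dn:
        raise EmptyScreenError(f"reference screen {assignment.reference} has no accepted reads")
    ref_mode = nonzero_mode(ref_dn.values())
    out: dict[str, NormalizedScreen] = {
        assignment.reference: NormalizedScreen(
            screen_id=assignment.reference,
            values=ref_dn,
            total_reads_used=ref_table.stats.total_reads,
            nonzero_mode=ref_mode,
        )
    }
    for sid in (*assignment.positives, *assignment.negatives):
        t = tables[sid]
        out[sid] = reference_normalize(
            sid,
            depth_normalize(t),
            ref_dn,
            ref_mode,
            total_reads_used=t.stats.total_reads,
        )
    return out


def build_matrix(
    screens: dict[str, NormalizedScreen],
    assignment: RoleAssignment,
    *,
    ubiquitous: bool = False,
) -> SelectivityMatrix:
    """Assemble and sort the comparison matrix.

    Rows are the union of peptides observed in the positive and negative
    screens (reference-only peptides were never selected and are excluded from
    ranking). Absent cells are filled with the owning screen's non-zero mode
    and flagged imputed. In the default mode the sort key is the selectivity
    ratio mean(positives)/mean(negatives); in ubiquitous mode it is the row
    minimum across all positive and negative screens, which surfaces peptides
    high everywhere (binders of every cell type, or non-specific).
    """
    missing = [s for s in assignment.screens if s not in screens]
    if missing:
        raise ConfigurationError(f"missing normalized screens: {missing}")
    if not ubiquitous and not assignment.negatives:
        raise ConfigurationError(
            "negative screens are required for the selectivity ratio; "
            "use ubiquitous mode to rank without negatives"
        )
    sel_cols = [*assignment.positives, *assignment.negatives]
    universe = sorted(set().union(*(screens[s].values.keys() for s in sel_cols)))
    if not universe:
        raise EmptyScreenError("no peptides observed in any positive or negative screen")

    cols = [assignment.reference, *sel_cols]
    data = pd.DataFrame(
        {sid: pd.Series(screens[sid].values, dtype=float) for sid in cols},
        index=pd.Index(universe, name="peptide"),
        columns=cols,
    )
    imputed = data.isna()
    modes = {sid: screens[sid].nonzero_mode for sid in cols}
    data = data.fillna(pd.Series(modes))

    pos = data[list(assignment.positives)]
    pos_mean = pos.mean(axis=1)
    positives_observed = (~imputed[list(assignment.positives)]).sum(axis=1)
    if ubiquitous:
        ratio = data[sel_cols].min(axis=1)
    else:
        neg_mean = data[list(assignment.negatives)].mean(axis=1)
        ratio = pos_mean / neg_mean
    matrix = SelectivityMatrix(
        data=data,
        imputed=imputed,
        ratio=ratio.rename(_RATIO_COL),
        pos_mean=pos_mean,
        positives_observed=positives_observed,
        assignment=assignment,
        ubiquitous=ubiquitous,
    )
    return sort_matrix(matrix)


def sort_matrix(matrix: SelectivityMatrix) -> SelectivityMatrix:
    """Stable sort: ratio descending, then mean positive value descending,
    then lexicographic peptide — a fully deterministic output order."""
    order = pd.DataFrame(
        {"r": matrix.ratio, "pm": matrix.pos_mean, "pep": matrix.data.index}
    ).sort_values(["r", "pm", "pep"], ascending=[False, False, True], kind="mergesort")
    idx = order.index
    return SelectivityMatrix(
        data=matrix.data.loc[idx],
        imputed=matrix.imputed.loc[idx],
        ratio=matrix.ratio.loc[idx],
        pos_mean=matrix.pos_mean.loc[idx],
        positives_observed=matrix.positives_observed.loc[idx],
        assignment=matrix.assignment,
        ubiquitous=matrix.ubiquitous,
    )


def resort_with_roles(
    tables: dict[str, ScreenTable],
    new_assignment: RoleAssignment,
    *,
    ubiquitous: bool = False,
) -> SelectivityMatrix:
    """Re-rank already-processed screens under a new role assignment.

    Works entirely from count tables — no FASTQ re-processing. Normalization is
    redone from the tables because the reference (and hence every denominator)
    may have changed with the roles.
    """
    fresh = normalize_screens(tables, new_assignment)
    return build_matrix(fresh, new_assignment, ubiquitous=ubiquitous)


def round_enrichment(
    round1: dict[str, NormalizedScreen],
    round2: dict[str, NormalizedScreen],
    positives1: list[str] | tuple[str, ...],
    positives2: list[str] | tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Per-peptide fold change from biopanning round 1 to round 2.

    mean round-2 normalized frequency across positive screens divided by the
    round-1 equivalent, with each round's screens imputing absences by their
    own non-zero mode. Each round must have been normalized against its own
    reference library.
    """
    if positives2 is None:
        positives2 = positives1
    peps1 = set().union(*(round1[s].values.keys() for s in positives1)) if positives1 else set()
    peps2 = set().union(*(round2[s].values.keys() for s in positives2)) if positives2 else set()
    shared = peps1 | peps2
    if not shared:
        logger.warning("round_enrichment: no peptides in either round's positive screens")
        return {}

    def mean_over(screens_map, sids, pep):
        return sum(
            screens_map[s].values.get(pep, screens_map[s].nonzero_mode) for s in sids
        ) / len(sids)

    return {
        p: mean_over(round2, positives2, p) / mean_over(round1, positives1, p)
        for p in sorted(shared)
    }


def export_matrix(
    matrix: SelectivityMatrix,
    path: str | Path,
    top_n: int | None = None,
    *,
    mask_path: str | Path | None = None,
    heatmap_path: str | Path | None = None,
) -> None:
    """Write the sorted matrix as TSV (+ imputation mask, optional heatmap).

    Columns: peptide, ratio, positives_observed, then one column per screen in
    reference/positives/negatives order. Ratios and frequencies are written
    with 12 significant digits so a read-back reproduces them. ``top_n`` limits
    the exported rows (the heat-map figures of this workflow typically show the
    top 40); the mask file always covers the same rows.
    """
    path = Path(path)
    if mask_path is None:
        mask_path = path.with_name(path.stem + ".imputed" + path.suffix)
    rows = matrix.data if top_n is None else matrix.data.iloc[:top_n]
    out = rows.copy()
    out.insert(0, _RATIO_COL, matrix.ratio.loc[rows.index])
    out.insert(1, "positives_observed", matrix.positives_observed.loc[rows.index])
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    matrix.imputed.loc[rows.index].astype(int).to_csv(mask_path, sep="\t")
    if heatmap_path is not None:
        _render_heatmap(matrix, rows.index, heatmap_path)


def _render_heatmap(matrix: SelectivityMatrix, index, heatmap_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    block = matrix.data.loc[index]
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.5 * block.shape[1], 1.0 + 0.18 * block.shape[0])
    )
    im = ax.imshow(np.log10(block.to_numpy()), aspect="auto", cmap="RdYlBu_r")
    ax.set_xticks(range(block.shape[1]), block.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(block.shape[0]), block.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log10 normalized frequency")
    fig.tight_layout()
    fig.savefig(heatmap_path, dpi=150)
    plt.close(fig)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read back an exported matrix TSV (peptide-indexed)."""
    return pd.read_csv(path, sep="\t", index_col="peptide")
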