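"""Built-in validation exercises for the ranking pipeline.

Two desk-scale experiments ship with the package:

* :func:`toy_screens` — an eight-peptide absent/low/high (A/L/H) sorting
  fixture over a reference, two positive and two negative screens, with a
  hand-derivable predicted ordering. Frequencies are 0 (absent), 10 (low) or
  1000 (high) with equal per-screen totals, so every normalized value and
  ratio can be checked by plain arithmetic.
* :func:`spike_recovery_experiment` — a full closed loop over the simulator
  and both pipeline parts: simulated reference/positive/negative screens with
  known target-selective spikes and parasitic amplifiers, measuring whether
  the selective clones reach the top fraction of the comparison matrix and the
  parasitic ones do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .extract import ScreenStats, ScreenTable, process_screen
from .scheme import LibraryScheme, make_scheme, translate_insert
from .selection import (
    RoleAssignment,
    SelectivityMatrix,
    build_matrix,
    normalize_screens,
    round_enrichment,
)
from .simulate import ScreenSimSpec, generate_naive_pool, simulate_round2, simulate_screen

# ---------------------------------------------------------------------------
# A/L/H toy sorting fixture
# ---------------------------------------------------------------------------

ABSENT, LOW, HIGH = 0, 10, 1000
_TOY_TOTAL = 10_000  # equal per-screen totals

#: Eight test patterns over (reference, P1, P2, N1, N2). Four are classic
#: cases with a stated qualitative prediction: a clone high in both positives
#: and absent elsewhere (GVTHKLQ) must rank first; one high only in the
#: negatives (TPSIYFL) last; one high in a positive but also in a negative
#: (RVSTPPQ) mid-table; one high everywhere but low in the reference
#: (SSDAALH) low, because the positive/negative ratio cancels. The other four
#: fill out the matrix: a half-selective clone, two reference-high clones with
#: different negative profiles, and a parasitic clone high everywhere
#: including the reference.
TOY_PATTERNS: dict[str, tuple[int, int, int, int, int]] = {
    "GVTHKLQ": (ABSENT, HIGH, HIGH, ABSENT, ABSENT),
    "HGFNNAQ": (LOW, HIGH, ABSENT, LOW, ABSENT),
    "WDPAKTF": (HIGH, HIGH, HIGH, LOW, LOW),
    "MQNVGSE": (HIGH, HIGH, HIGH, HIGH, LOW),
    "RVSTPPQ": (LOW, ABSENT, HIGH, HIGH, ABSENT),
    "SSDAALH": (LOW, HIGH, HIGH, HIGH, HIGH),
    "YGAKDNL": (HIGH, HIGH, HIGH, HIGH, HIGH),
    "TPSIYFL": (ABSENT, ABSENT, ABSENT, HIGH, HIGH),
}

#: Ordering implied by the patterns under this pipeline's exact arithmetic
#: (derivable by hand; re-derived independently in the test suite).
TOY_PREDICTED_ORDER = [
    "GVTHKLQ",
    "HGFNNAQ",
    "WDPAKTF",
    "MQNVGSE",
    "RVSTPPQ",
    "SSDAALH",
    "YGAKDNL",
    "TPSIYFL",
]

TOY_SCREEN_IDS = ("ref", "pos1", "pos2", "neg1", "neg2")


def toy_screens() -> tuple[dict[str, ScreenTable], RoleAssignment]:
    """Screen tables for the A/L/H sorting fixture."""
    tables: dict[str, ScreenTable] = {}
    for col, sid in enumerate(TOY_SCREEN_IDS):
        counts = {
            pep: pattern[col] for pep, pattern in TOY_PATTERNS.items() if pattern[col] > 0
        }
        tables[sid] = ScreenTable(
            screen_id=sid,
            scheme_name="toy",
            counts=counts,
            stats=ScreenStats(
                total_reads=_TOY_TOTAL,
                accepted_reads=sum(counts.values()),
                rejected_no_flank=_TOY_TOTAL - sum(counts.values()),
                unique_peptides=len(counts),
            ),
        )
    assignment = RoleAssignment(reference="ref", positives=("pos1", "pos2"), negatives=("neg1", "neg2"))
    return tables, assignment


def toy_matrix() -> SelectivityMatrix:
    """Run the A/L/H fixture through normalization, imputation and sorting."""
    tables, assignment = toy_screens()
    return build_matrix(normalize_screens(tables, assignment), assignment)


# ---------------------------------------------------------------------------
# Spiked-recovery experiment
# ---------------------------------------------------------------------------


@dataclass
class SpikeRecoveryResult:
    """Outcome of one seeded spiked-recovery run."""

    selective_peptides: list[str]
    parasitic_peptides: list[str]
    ranks: dict[str, int]  # 1-based rank in the sorted matrix
    n_rows: int
    all_selective_in_top_fraction: bool
    parasitic_in_top_fraction: list[str]
    matrix: SelectivityMatrix


def _choose_clones(pool: dict[str, float], rng: np.random.Generator, n: int, exclude=()) -> list[str]:
    # Spiked clones are drawn from the upper half of the naive abundance
    # distribution: clones recovered from panning are, by construction,
    # clones that were actually present at samplable abundance.
    median = float(np.median(list(pool.values())))
    candidates = sorted(ins for ins, w in pool.items() if w >= median and ins not in exclude)
    picks = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picks)]


def spike_recovery_experiment(
    seed: int,
    work_dir: str | Path,
    *,
    n_reads: int = 100_000,
    n_pool: int = 20_000,
    skew_sigma: float = 1.2,
    n_positive: int = 3,
    n_negative: int = 3,
    n_selective: int = 5,
    n_parasitic: int = 5,
    selective_factor: float = 50.0,
    parasitic_factor: float = 20.0,
    error_rate: float = 0.001,
    top_fraction: float = 0.01,
    scheme: LibraryScheme | None = None,
) -> SpikeRecoveryResult:
    """Simulate one full screen set and measure spike recovery.

    Selective clones are enriched ``selective_factor``-fold in the positive
    screens only; parasitic clones are amplified ``parasitic_factor``-fold in
    *every* screen including the reference (amplification bias acts wherever
    the library is grown in bacteria). Success means every selective peptide
    ranks inside the top ``top_fraction`` of matrix rows and no parasitic-only
    clone does.
    """
    if scheme is None:
        scheme = make_scheme("NEB-PhD7")
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pool = generate_naive_pool(n_pool, skew_sigma, scheme, seed=int(rng.integers(2**31)))
    selective = _choose_clones(pool, rng, n_selective)
    parasitic = _choose_clones(pool, rng, n_parasitic, exclude=set(selective))
    spikes = {ins: selective_factor for ins in selective}
    paras = {ins: parasitic_factor for ins in parasitic}

    roles: list[tuple[str, dict[str, float]]] = [("ref", {})]
    roles += [(f"pos{i+1}", spikes) for i in range(n_positive)]
    roles += [(f"neg{i+1}", {}) for i in range(n_negative)]

    tables = {}
    for sid, spike_map in roles:
        spec = ScreenSimSpec(
            n_reads=n_reads,
            naive_pool=pool,
            scheme=scheme,
            seed=int(rng.integers(2**31)),
            selective_spikes=spike_map,
            parasitic_clones=paras,
            error_rate=error_rate,
        )
        fq = work_dir / f"{sid}.fastq"
        simulate_screen(spec, fq)
        tables[sid] = process_screen(fq, scheme, sid)
        fq.unlink()  # keep the workspace small

    assignment = RoleAssignment(
        reference="ref",
        positives=tuple(f"pos{i+1}" for i in range(n_positive)),
        negatives=tuple(f"neg{i+1}" for i in range(n_negative)),
    )
    matrix = build_matrix(normalize_screens(tables, assignment), assignment)

    sel_peps = [translate_insert(ins, scheme) for ins in selective]
    par_peps = [translate_insert(ins, scheme) for ins in parasitic]
    rank_of = {pep: i + 1 for i, pep in enumerate(matrix.peptides)}
    n_rows = len(matrix.peptides)
    cutoff = max(1, int(np.ceil(top_fraction * n_rows)))
    ranks = {p: rank_of.get(p, n_rows + 1) for p in sel_peps + par_peps}
    return SpikeRecoveryResult(
        selective_peptides=sel_peps,
        parasitic_peptides=par_peps,
        ranks=ranks,
        n_rows=n_rows,
        all_selective_in_top_fraction=all(ranks[p] <= cutoff for p in sel_peps),
        parasitic_in_top_fraction=[p for p in par_peps if ranks[p] <= cutoff],
        matrix=matrix,
    )


def two_round_enrichment_experiment(
    seed: int,
    work_dir: str | Path,
    *,
    n_reads: int = 50_000,
    n_pool: int = 5_000,
    skew_sigma: float = 1.0,
    n_selective: int = 5,
    selective_factor: float = 8.0,
    scheme: LibraryScheme | None = None,
) -> dict[str, float]:
    """Measure round-1 -> round-2 fold change for clones with a known per-round factor.

    One positive screen per round plus a per-round reference (the reference is
    amplified alongside each round). With per-round enrichment e, the measured
    round-2/round-1 normalized-frequency ratio of a spiked clone should be ~e.
    Returns the measured enrichment for each spiked peptide.
    """
    if scheme is None:
        scheme = make_scheme("NEB-PhD7")
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pool = generate_naive_pool(n_pool, skew_sigma, scheme, seed=int(rng.integers(2**31)))
    selective = _choose_clones(pool, rng, n_selective)
    spikes = {ins: selective_factor for ins in selective}

    def run_round(tag: str, pos_pool: dict[str, float]):
        # Each round sequences a freshly amplified *unselected* reference
        # aliquot alongside its positive screen.
        tables = {}
        for sid, pl, spike_map in (
            (f"ref_{tag}", pool, {}),
            (f"pos_{tag}", pos_pool, spikes),
        ):
            spec = ScreenSimSpec(
                n_reads=n_reads,
                naive_pool=pl,
                scheme=scheme,
                seed=int(rng.integers(2**31)),
                selective_spikes=spike_map,
            )
            fq = work_dir / f"{sid}.fastq"
            simulate_screen(spec, fq)
            tables[sid] = process_screen(fq, scheme, sid)
            fq.unlink()
        assignment = RoleAssignment(reference=f"ref_{tag}", positives=(f"pos_{tag}",))
        return normalize_screens(tables, assignment), assignment

    # Round 1 pans the naive pool; round 2 pans round 1's enriched output.
    r1_spec = ScreenSimSpec(
        n_reads=n_reads, naive_pool=pool, scheme=scheme, seed=0, selective_spikes=spikes
    )
    pool_r2 = simulate_round2(r1_spec, seed=0).naive_pool
    norm1, asg1 = run_round("r1", pool)
    norm2, asg2 = run_round("r2", pool_r2)

    enrich = round_enrichment(norm1, norm2, asg1.positives, asg2.positives)
    return {translate_insert(ins, scheme): enrich[translate_insert(ins, scheme)] for ins in selective}
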