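"""Synthetic phage-display screens with the statistical structure the analysis assumes.

The generator emulates four features of real biopanning NGS data:

* a *skewed naive library* — clone abundances drawn log-normally, because the
  starting distribution of commercial display libraries is far from uniform;
* *parasitic clones* — sequences whose bacterial amplification advantage
  inflates them in every screen, including the unselected reference aliquot;
* *target-selective enrichment* — per-clone spike factors applied only in the
  screens panned against the clone's target;
* *sequencing error* — independent per-base substitutions over the whole read
  (no indels: an indel would break flank anchoring and conflate two distinct
  failure modes in tests).

Reads are emitted as ``pad5 + flank5 + insert + flank3 + pad3`` inside a
fixed-length template with primer-like padding, so that extraction must
genuinely search for the flanks rather than slice fixed offsets. Quality lines
are constant ('I'): the pipeline ignores quality, so fixture realism there
buys nothing. Everything is deterministic per seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .scheme import AMBER, STOP_CODONS, LibraryScheme, allowed_codons

DEFAULT_PAD5 = "GTACCTTTCTAT"
DEFAULT_PAD3 = "TTCGGCCGAACC"

_BASES = "ACGT"
_ALT = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass
class ScreenSimSpec:
    """Parameters of one simulated screen.

    ``naive_pool`` maps insert DNA to abundance weight; sampling probability is
    proportional to weight x selective spike factor x parasitic amplification
    factor. Factors default to 1 for inserts not listed.
    """

    n_reads: int
    naive_pool: dict[str, float]
    scheme: LibraryScheme
    seed: int
    selective_spikes: dict[str, float] = field(default_factory=dict)
    parasitic_clones: dict[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    pad5: str = DEFAULT_PAD5
    pad3: str = DEFAULT_PAD3

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError(f"n_reads must be >= 0, got {self.n_reads}")
        if not self.naive_pool:
            raise ValueError("naive_pool must be non-empty")
        if any(w <= 0 for w in self.naive_pool.values()):
            raise ValueError("naive pool weights must be strictly positive")
        for name, factors in (
            ("selective_spikes", self.selective_spikes),
            ("parasitic_clones", self.parasitic_clones),
        ):
            if any(f < 1 for f in factors.values()):
                raise ValueError(f"{name} factors must be >= 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError(f"error_rate must be in [0, 0.1], got {self.error_rate}")


def codon_space_size(scheme: LibraryScheme) -> int:
    """Number of distinct stop-free inserts the scheme's codon constraint allows."""
    terminators = STOP_CODONS - {AMBER} if scheme.amber_as_gln else STOP_CODONS
    per_codon = len(allowed_codons(scheme.codon_constraint) - terminators)
    return per_codon ** scheme.peptide_length


def generate_naive_pool(
    n_unique: int, skew_sigma: float, scheme: LibraryScheme, seed: int
) -> dict[str, float]:
    """Draw ``n_unique`` distinct constraint-valid inserts with log-normal weights.

    ``skew_sigma`` is the sigma of the underlying normal; 0 gives a perfectly
    even library, ~1–1.5 matches the heavy skew of real naive libraries. Stop
    codons are never emitted (library members display complete peptides; for
    NNK schemes TAA/TGA are unreachable anyway and TAG is read through).
    """
    if n_unique < 1:
        raise ValueError(f"n_unique must be >= 1, got {n_unique}")
    space = codon_space_size(scheme)
    if n_unique > space:
        raise ValueError(f"n_unique {n_unique} exceeds the {space} possible inserts")
    rng = np.random.default_rng(seed)
    terminators = STOP_CODONS - {AMBER} if scheme.amber_as_gln else STOP_CODONS
    codons = np.array(sorted(allowed_codons(scheme.codon_constraint) - terminators))

    k = scheme.peptide_length
    pool: set[str] = set()
    while len(pool) < n_unique:
        need = n_unique - len(pool)
        batch = max(need + 16, int(need * 1.1))
        idx = rng.integers(0, len(codons), size=(batch, k))
        for row in idx:
            pool.add("".join(codons[row]))
            if len(pool) == n_unique:
                break
    ordered = sorted(pool)
    if skew_sigma == 0:
        weights = np.ones(n_unique)
    else:
        weights = rng.lognormal(mean=0.0, sigma=skew_sigma, size=n_unique)
    return dict(zip(ordered, weights))


def effective_weights(spec: ScreenSimSpec) -> dict[str, float]:
    """Naive weight x spike x amplification for every pool member."""
    return {
        ins: w
        * spec.selective_spikes.get(ins, 1.0)
        * spec.parasitic_clones.get(ins, 1.0)
        for ins, w in spec.naive_pool.items()
    }


def simulate_screen(spec: ScreenSimSpec, path: str | Path) -> Path:
    """Sample reads for one screen and write them as FASTQ (gzip if ``.gz``).

    Read counts per clone are multinomial in the effective weights;
    substitution errors are applied uniformly over all read positions at
    ``spec.error_rate`` per base; read order is shuffled. Deterministic per
    ``spec.seed``.
    """
    path = Path(path)
    rng = np.random.default_rng(spec.seed)
    inserts = list(spec.naive_pool)
    w = np.fromiter(effective_weights(spec).values(), dtype=float, count=len(inserts))
    probs = w / w.sum()
    counts = rng.multinomial(spec.n_reads, probs)

    prefix = spec.pad5 + spec.scheme.flank5
    suffix = spec.scheme.flank3 + spec.pad3
    reads: list[str] = []
    for ins, c in zip(inserts, counts):
        if c:
            reads.extend([prefix + ins + suffix] * int(c))

    read_len = len(prefix) + spec.scheme.insert_length + len(suffix)
    if spec.error_rate > 0 and reads:
        n_bases = len(reads) * read_len
        n_err = rng.binomial(n_bases, spec.error_rate)
        if n_err:
            flat = rng.integers(0, n_bases, size=n_err)
            picks = rng.integers(0, 3, size=n_err)
            for f, pick in zip(flat, picks):
                r, pos = divmod(int(f), read_len)
                s = reads[r]
                reads[r] = s[:pos] + _ALT[s[pos]][pick] + s[pos + 1 :]

    order = rng.permutation(len(reads))
    qual = "I" * read_len
    lines = []
    for out_i, r in enumerate(order):
        lines.append(f"@sim:{spec.seed}:{out_i}\n{reads[r]}\n+\n{qual}")
    payload = "\n".join(lines) + ("\n" if lines else "")
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(payload)
    else:
        with open(path, "w") as fh:
            fh.write(payload)
    return path


def simulate_round2(round1_spec: ScreenSimSpec, seed: int) -> ScreenSimSpec:
    """Spec for a second biopanning round seeded by round 1's enriched pool.

    The round-2 naive pool is round 1's pool scaled by its spike and
    amplification factors (the expected post-selection, post-amplification
    distribution); the same factors then apply again during round 2, so a
    clone with per-round factor e is enriched ~e^2 over two rounds.
    """
    return replace(round1_spec, naive_pool=effective_weights(round1_spec), seed=seed)


def write_ground_truth(spec: ScreenSimSpec, path: str | Path) -> None:
    """TSV of true abundances and factors for every pool member."""
    from .scheme import translate_insert

    with open(path, "w") as fh:
        fh.write("insert\tpeptide\tweight\tselective_spike\tparasitic_factor\n")
        for ins in sorted(spec.naive_pool):
            pep = translate_insert(ins, spec.scheme) or "*stop*"
            fh.write(
                f"{ins}\t{pep}\t{spec.naive_pool[ins]:.10g}"
                f"\t{spec.selective_spikes.get(ins, 1.0):.10g}"
                f"\t{spec.parasitic_clones.get(ins, 1.0):.10g}\n"
            )
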