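"""Shared fixtures: schemes, FASTQ writers, and an independent counting oracle.

The oracle functions here deliberately re-implement the read-classification
contract from scratch (position-by-position slicing, Biopython whole-string
translation, explicitly enumerated NNK codons) so that pipeline results can be
cross-checked against a second, structurally different implementation.
"""

from __future__ import annotations

import random
from itertools import product
from pathlib import Path

import pytest
from Bio.Seq import Seq

from selpep import LibraryScheme, ScreenStats, make_scheme

PAD5 = "GTACCTTTCTAT"
PAD3 = "TTCGGCCGAACC"

NNK_CODONS = sorted(
    "".join(c) for c in product("ACGT", "ACGT", "GT")
)  # 32 by construction


@pytest.fixture(scope="session")
def phd7() -> LibraryScheme:
    return make_scheme("NEB-PhD7")


@pytest.fixture(scope="session")
def phd7_nofilter() -> LibraryScheme:
    return make_scheme("NEB-PhD7", codon_filter=False)


def write_fastq(path: Path, seqs: list[str]) -> Path:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@read{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path


def read_for_insert(insert: str, pad5: str = PAD5, pad3: str = PAD3) -> str:
    return pad5 + "TCT" + insert + "GGAGGTGGA" + pad3


def random_nnk_insert(rng: random.Random, k: int = 7) -> str:
    return "".join(rng.choice(NNK_CODONS) for _ in range(k))


def make_adversarial_reads(seed: int, n_reads: int) -> list[str]:
    """A mixed bag of valid, flankless, ambiguous and codon-breaking reads."""
    rng = random.Random(seed)
    reads: list[str] = []
    # a few recurring clones so counts above 1 occur
    clones = [random_nnk_insert(rng) for _ in range(max(3, n_reads // 50))]
    for _ in range(n_reads):
        kind = rng.random()
        if kind < 0.55:  # valid read of a recurring clone
            reads.append(read_for_insert(rng.choice(clones)))
        elif kind < 0.65:  # valid read, fresh insert
            reads.append(read_for_insert(random_nnk_insert(rng)))
        elif kind < 0.72:  # N inside the insert
            ins = list(random_nnk_insert(rng))
            ins[rng.randrange(len(ins))] = "N"
            reads.append(read_for_insert("".join(ins)))
        elif kind < 0.79:  # non-NNK third base in one codon
            ins = list(random_nnk_insert(rng))
            pos = 3 * rng.randrange(7) + 2
            ins[pos] = rng.choice("AC")
            reads.append(read_for_insert("".join(ins)))
        elif kind < 0.85:  # broken 3' flank
            r = read_for_insert(random_nnk_insert(rng))
            j = len(PAD5) + 3 + 21 + rng.randrange(9)
            reads.append(r[:j] + {"A": "C", "C": "A", "G": "T", "T": "G"}[r[j]] + r[j + 1 :])
        elif kind < 0.90:  # broken 5' flank
            r = read_for_insert(random_nnk_insert(rng))
            j = len(PAD5) + rng.randrange(3)
            reads.append(r[:j] + {"A": "C", "C": "A", "G": "T", "T": "G"}[r[j]] + r[j + 1 :])
        elif kind < 0.95:  # too short
            reads.append(read_for_insert(random_nnk_insert(rng))[: rng.randrange(5, 30)])
        else:  # decoy flank3 occurrence before the real one, no 5' flank there
            ins = random_nnk_insert(rng)
            reads.append("GGAGGTGGA" + "A" * 16 + "TCT" + ins + "GGAGGTGGA" + PAD3)
    return reads


def oracle_classify(seq: str, scheme: LibraryScheme) -> tuple[str | None, str]:
    """Independent re-implementation: returns (peptide or None, outcome bin)."""
    s = seq.upper()
    k5, L3 = len(scheme.flank5), len(scheme.flank3)
    ins_len = scheme.insert_length
    insert = None
    for idx in range(ins_len + k5, len(s) - L3 + 1):
        if s[idx : idx + L3] != scheme.flank3:
            continue
        if s[idx - ins_len - k5 : idx - ins_len] == scheme.flank5:
            insert = s[idx - ins_len : idx]
            break
        # flank3 seen but 5' signature absent: keep scanning rightward
    if insert is None:
        return None, "no_flank"
    if any(ch not in "ACGT" for ch in insert):
        return None, "ambiguous_base"
    codons = [insert[i : i + 3] for i in range(0, ins_len, 3)]
    if scheme.codon_filter and scheme.codon_constraint == "NNK":
        if any(c not in NNK_CODONS for c in codons):
            return None, "codon_constraint"
    prot = str(Seq(insert).translate())
    if "*" in prot:
        fixed = list(prot)
        for i, aa in enumerate(prot):
            if aa == "*":
                if scheme.amber_as_gln and codons[i] == "TAG":
                    fixed[i] = "Q"
                else:
                    return None, "stop"
        prot = "".join(fixed)
    return prot, "accepted"


def oracle_recount(seqs: list[str], scheme: LibraryScheme):
    """Brute-force counts and five-way stats partition for a list of reads."""
    counts: dict[str, int] = {}
    bins = {"accepted": 0, "no_flank": 0, "ambiguous_base": 0, "codon_constraint": 0, "stop": 0}
    for s in seqs:
        pep, outcome = oracle_classify(s, scheme)
        bins[outcome] += 1
        if pep is not None:
            counts[pep] = counts.get(pep, 0) + 1
    stats = ScreenStats(
        total_reads=len(seqs),
        accepted_reads=bins["accepted"],
        rejected_no_flank=bins["no_flank"],
        rejected_ambiguous_base=bins["ambiguous_base"],
        rejected_codon_constraint=bins["codon_constraint"],
        rejected_stop=bins["stop"],
        unique_peptides=len(counts),
    )
    return counts, stats
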