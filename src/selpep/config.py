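"""Run configuration, the two-part pipeline driver, and report generation.

A run configuration (YAML or JSON) names the library scheme, lists the screens
with their input files (FASTQ for fresh extraction, or a counts CSV from a
previous run for re-sorting), assigns each the role reference / positive /
negative, and sets the processing options. A reference screen is mandatory:
without the unselected amplified library there is no background to divide out,
and parasitic amplifiers masquerade as binders.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .extract import ScreenTable, process_screen, read_screen_table, write_screen_table
from .scheme import LibraryScheme, make_scheme
from .selection import (
    ConfigurationError,
    NormalizedScreen,
    RoleAssignment,
    SelectivityMatrix,
    build_matrix,
    export_matrix,
    normalize_screens,
)

logger = logging.getLogger(__name__)

ROLES = ("reference", "positive", "negative")


@dataclass
class ScreenEntry:
    screen_id: str
    role: str
    fastq: Path | None = None
    counts: Path | None = None


@dataclass
class RunConfig:
    """Fully resolved and validated run configuration."""

    scheme: LibraryScheme
    screens: list[ScreenEntry]
    out_dir: Path = Path(".")
    codon_filter: bool | None = None  # None: use the scheme's default
    try_revcomp: bool = False
    top_n: int | None = 40
    ubiquitous: bool = False
    heatmap: bool = False

    @property
    def assignment(self) -> RoleAssignment:
        return RoleAssignment(
            reference=next(s.screen_id for s in self.screens if s.role == "reference"),
            positives=tuple(s.screen_id for s in self.screens if s.role == "positive"),
            negatives=tuple(s.screen_id for s in self.screens if s.role == "negative"),
        )


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _resolve_scheme(node) -> LibraryScheme:
    if isinstance(node, str):
        return make_scheme(node)
    if isinstance(node, dict):
        return make_scheme(
            node.get("name", "custom"),
            flank5=node.get("flank5"),
            flank3=node.get("flank3"),
            peptide_length=node.get("peptide_length"),
            codon_constraint=node.get("constraint", node.get("codon_constraint")),
            amber_as_gln=node.get("amber_as_gln"),
            codon_filter=node.get("codon_filter"),
        )
    raise ConfigurationError(f"scheme must be a preset name or a mapping, got {node!r}")


def validate_config(path: str | Path) -> RunConfig:
    """Parse, resolve and role-check a run configuration file."""
    path = Path(path)
    try:
        raw = _load_structured(path)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"{path}: cannot parse configuration: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")

    scheme = _resolve_scheme(raw.get("scheme", "NEB-PhD7"))
    entries: list[ScreenEntry] = []
    seen: set[str] = set()
    for node in raw.get("screens", []):
        sid = node.get("id")
        role = node.get("role")
        if not sid:
            raise ConfigurationError(f"{path}: screen entry without id: {node}")
        if sid in seen:
            raise ConfigurationError(f"{path}: duplicate screen id {sid!r}")
        seen.add(sid)
        if role not in ROLES:
            raise ConfigurationError(f"{path}: screen {sid!r} has invalid role {role!r}")
        fastq = node.get("fastq")
        counts = node.get("counts")
        if (fastq is None) == (counts is None):
            raise ConfigurationError(
                f"{path}: screen {sid!r} needs exactly one of 'fastq' or 'counts'"
            )
        src = Path(fastq or counts)
        if not src.is_absolute():
            src = path.parent / src
        if not src.exists():
            raise ConfigurationError(f"{path}: screen {sid!r}: input {src} does not exist")
        entries.append(
            ScreenEntry(
                screen_id=sid,
                role=role,
                fastq=src if fastq else None,
                counts=src if counts else None,
            )
        )

    roles = [e.role for e in entries]
    if roles.count("reference") != 1:
        raise ConfigurationError(
            f"{path}: exactly one reference screen is required, found {roles.count('reference')}"
        )
    if roles.count("positive") == 0:
        raise ConfigurationError(f"{path}: at least one positive screen is required")

    opts = raw.get("options", {}) or {}
    cfg = RunConfig(
        scheme=scheme,
        screens=entries,
        out_dir=Path(raw.get("out_dir", ".")),
        codon_filter=opts.get("codon_filter"),
        try_revcomp=bool(opts.get("try_revcomp", False)),
        top_n=opts.get("top_n", 40),
        ubiquitous=bool(opts.get("ubiquitous", False)),
        heatmap=bool(opts.get("heatmap", False)),
    )
    logger.info(
        "resolved config %s: scheme=%s screens=%d (%s) options=%s",
        path, scheme.name, len(entries),
        ",".join(f"{e.screen_id}:{e.role}" for e in entries),
        {k: getattr(cfg, k) for k in ("codon_filter", "try_revcomp", "top_n", "ubiquitous")},
    )
    return cfg


def load_tables(cfg: RunConfig) -> dict[str, ScreenTable]:
    """Extract (FASTQ inputs) or read back (counts inputs) every screen."""
    scheme = cfg.scheme
    if cfg.codon_filter is not None and cfg.codon_filter != scheme.codon_filter:
        scheme = make_scheme(
            scheme.name,
            flank5=scheme.flank5,
            flank3=scheme.flank3,
            peptide_length=scheme.peptide_length,
            codon_constraint=scheme.codon_constraint,
            amber_as_gln=scheme.amber_as_gln,
            codon_filter=cfg.codon_filter,
        )
    tables: dict[str, ScreenTable] = {}
    for entry in cfg.screens:
        if entry.fastq is not None:
            tables[entry.screen_id] = process_screen(
                entry.fastq, scheme, entry.screen_id, try_revcomp=cfg.try_revcomp
            )
        else:
            tables[entry.screen_id] = read_screen_table(
                entry.counts, screen_id=entry.screen_id
            )
    return tables


def run_report(
    tables: dict[str, ScreenTable],
    normalized: dict[str, NormalizedScreen],
    assignment: RoleAssignment,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the per-screen summary table and replicate-agreement scatter data.

    ``summary.tsv`` mirrors the run-summary tables of this workflow (screen,
    role, total reads, accepted reads, unique peptides). When a role group has
    two or more screens (replicates of the same target), ``replicate_scatter.tsv``
    holds one row per (peptide, replicate) pair with the replicate's normalized
    frequency and the imputed group mean, the data behind replicate-agreement
    scatter plots.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    role_of = {assignment.reference: "reference"}
    role_of.update({s: "positive" for s in assignment.positives})
    role_of.update({s: "negative" for s in assignment.negatives})
    rows = []
    for sid in assignment.screens:
        st = tables[sid].stats
        rows.append(
            {
                "screen_id": sid,
                "role": role_of[sid],
                "total_reads": st.total_reads,
                "accepted_reads": st.accepted_reads,
                "unique_peptides": st.unique_peptides,
            }
        )
    summary = pd.DataFrame(rows)
    outputs["summary"] = out_dir / "summary.tsv"
    summary.to_csv(outputs["summary"], sep="\t", index=False)

    scatter_rows = []
    for role, group in (("positive", assignment.positives), ("negative", assignment.negatives)):
        if len(group) < 2:
            continue
        for sid in group:
            screen = normalized[sid]
            for pep in sorted(screen.values):
                mean = sum(
                    normalized[o].values.get(pep, normalized[o].nonzero_mode) for o in group
                ) / len(group)
                scatter_rows.append(
                    {
                        "peptide": pep,
                        "role": role,
                        "screen_id": sid,
                        "value": screen.values[pep],
                        "group_mean": mean,
                    }
                )
    if scatter_rows:
        outputs["replicate_scatter"] = out_dir / "replicate_scatter.tsv"
        pd.DataFrame(scatter_rows).to_csv(
            outputs["replicate_scatter"], sep="\t", index=False, float_format="%.12g"
        )
    return outputs


def run_select(cfg: RunConfig) -> SelectivityMatrix:
    """Full part-2 run: load, normalize, rank, export, report, manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignment = cfg.assignment
    tables = load_tables(cfg)
    for sid, t in tables.items():
        write_screen_table(t, out_dir / f"{sid}.counts.csv")
    normalized = normalize_screens(tables, assignment)
    matrix = build_matrix(normalized, assignment, ubiquitous=cfg.ubiquitous)
    export_matrix(
        matrix,
        out_dir / "matrix.tsv",
        top_n=cfg.top_n,
        heatmap_path=out_dir / "heatmap.png" if cfg.heatmap else None,
    )
    reports = run_report(tables, normalized, assignment, out_dir)
    manifest = {
        "selpep_version": __version__,
        "scheme": cfg.scheme.name,
        "screens": [
            {"id": e.screen_id, "role": e.role, "input": str(e.fastq or e.counts)}
            for e in cfg.screens
        ],
        "options": {
            "codon_filter": cfg.codon_filter,
            "try_revcomp": cfg.try_revcomp,
            "top_n": cfg.top_n,
            "ubiquitous": cfg.ubiquitous,
        },
        "outputs": sorted(
            [p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"]
        ),
        "n_matrix_rows": len(matrix.peptides),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return matrix
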