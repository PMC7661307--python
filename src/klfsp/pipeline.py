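"""End-to-end orchestration and event-report rendering.

The pipeline wires the stages together: screen a proteome for family
candidates, build concatenated motif blocks for external alignment/tree
inference, reconcile supplied gene trees onto the species tree, run
copy-number parsimony, analyse gene architecture and synteny, apply
override directives, and render the per-branch event report (duplications
as ``*``, losses as ``X``).  Tree inference itself is consumed, never
invoked: gene trees and MCMC samples come from upstream tools.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from . import synteny as _syn
from .motifs import (
    ArchitecturePattern,
    DEFAULT_MOTIF_ORDER,
    DEFAULT_MOTIFS,
    MotifDefinition,
    annotate_motifs,
    build_concat_block,
    read_fasta,
    scan_architecture,
    screen_proteome,
    write_blocks_fasta,
)
from .reconcile import (
    CostModel,
    EventMap,
    OverrideDirective,
    ancestral_copy_number,
    combine_evidence,
    event_map_from_copy_number,
    event_map_from_reconciliation,
    lca_reconcile,
    read_gene_tree,
    read_species_tree,
)

log = logging.getLogger("klfsp")

EXIT_MISSING_INPUT = 2
EXIT_SCHEMA = 3
EXIT_STAGE = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = EXIT_STAGE):
        super().__init__(message)
        self.exit_code = exit_code


# ------------------------------------------------------------- rendering

def render_report(event_map: EventMap, retro_events=None, format: str = "text") -> str:
    """Serialize an event map (plus optional retro-event annotations).

    text — one line per branch: ``branch<TAB>stars<TAB>Xs<TAB>provenance``;
    json/tsv — lossless machine-readable forms, mutually convertible.
    """
    retro_by_branch: dict = {}
    for ev in retro_events or []:
        retro_by_branch[ev.node_branch] = retro_by_branch.get(ev.node_branch, 0) + 1
    rows = []
    for bid in sorted(event_map.branches):
        ev = event_map.branches[bid]
        rows.append(
            {
                "branch": bid,
                "duplications": ev.duplications,
                "losses": ev.losses,
                "provenance": ev.provenance,
                "retroduplications": retro_by_branch.get(bid, 0),
            }
        )
    if format == "json":
        return json.dumps({r["branch"]: {k: v for k, v in r.items() if k != "branch"} for r in rows},
                          indent=1, sort_keys=True)
    if format == "tsv":
        header = "branch\tduplications\tlosses\tprovenance\tretroduplications"
        lines = [header] + [
            f"{r['branch']}\t{r['duplications']}\t{r['losses']}\t{r['provenance']}\t{r['retroduplications']}"
            for r in rows
        ]
        return "\n".join(lines) + "\n"
    if format == "text":
        lines = ["branch\tduplications\tlosses\tprovenance"]
        for r in rows:
            stars = "*" * r["duplications"] or "-"
            xs = "X" * r["losses"] or "-"
            tag = r["provenance"] + (
                f" [{r['retroduplications']} retro]" if r["retroduplications"] else ""
            )
            lines.append(f"{r['branch']}\t{stars}\t{xs}\t{tag}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def report_from_tsv(text: str) -> dict:
    """Parse the TSV rendering back into {branch: counts} (round-trip)."""
    lines = [ln for ln in text.strip().splitlines() if ln]
    out = {}
    for ln in lines[1:]:
        branch, d, l, prov, retro = ln.split("\t")
        out[branch] = {
            "duplications": int(d),
            "losses": int(l),
            "provenance": prov,
            "retroduplications": int(retro),
        }
    return out


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    fasta: str | None = None
    species_tree: str | None = None
    gene_trees: list = field(default_factory=list)
    counts: str | None = None
    gff: str | None = None
    family_map: str | None = None
    out_dir: str = "pipeline_out"
    window: int = 1_500_000
    cost_model: CostModel = field(default_factory=CostModel)
    pattern: ArchitecturePattern = field(default_factory=ArchitecturePattern)
    motifs: tuple = DEFAULT_MOTIFS
    motif_order: tuple = DEFAULT_MOTIF_ORDER
    overrides: list = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"


def load_motifs_config(block: dict) -> tuple:
    return tuple(
        MotifDefinition(name, pattern, "config") for name, pattern in block.items()
    )


def load_architecture_config(block: dict) -> ArchitecturePattern:
    d_position = int(block.get("d_position", 44))
    if "spacers" in block:
        return ArchitecturePattern.from_spacers(
            [int(x) for x in block["spacers"]], d_position=d_position
        )
    return ArchitecturePattern(d_position=d_position)


def load_overrides_config(entries: list) -> list:
    out = []
    for e in entries:
        out.append(
            OverrideDirective(
                clade=e["clade"],
                replacement={
                    b: (int(v["duplications"]), int(v["losses"]))
                    for b, v in e.get("replacement", {}).items()
                },
                justification=e.get("justification", ""),
            )
        )
    return out


def load_config(path: str) -> PipelineConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise PipelineError(f"config file not found: {path}", EXIT_MISSING_INPUT)
    try:
        cfg = PipelineConfig()
        for key in ("fasta", "species_tree", "counts", "gff", "family_map", "out_dir", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.gene_trees = list(raw.get("gene_trees", []))
        cfg.window = int(raw.get("window", cfg.window))
        cfg.seed = int(raw.get("seed", cfg.seed))
        if "cost_model" in raw:
            cm = raw["cost_model"]
            cfg.cost_model = CostModel(
                gain_cost=float(cm.get("gain_cost", 1)),
                loss_cost=float(cm.get("loss_cost", 1)),
                max_copies=int(cm.get("max_copies", 8)),
            )
        if "motifs" in raw:
            cfg.motifs = load_motifs_config(raw["motifs"])
        if "architecture" in raw:
            cfg.pattern = load_architecture_config(raw["architecture"])
        if "overrides" in raw:
            cfg.overrides = load_overrides_config(raw["overrides"])
        return cfg
    except (KeyError, TypeError, ValueError) as exc:
        raise PipelineError(f"invalid config: {exc}", EXIT_SCHEMA) from exc


# --------------------------------------------------------------- pipeline

def _require(path: str | None, what: str) -> str:
    if not path:
        raise PipelineError(f"config is missing required input: {what}", EXIT_SCHEMA)
    if not os.path.exists(path):
        raise PipelineError(f"{what} not found: {path}", EXIT_MISSING_INPUT)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; writes every intermediate under ``cfg.out_dir``
    plus a manifest, and returns the manifest dict."""
    logging.basicConfig(level=cfg.log_level)
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "seed": cfg.seed}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = round(dt, 4)
                if exc_type is not None:
                    log.error("stage %s: FAILED after %.2fs", name, dt)
                    return False
                log.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    species = None
    if cfg.species_tree:
        species = read_species_tree(_require(cfg.species_tree, "species tree"))

    # screen + concat blocks
    if cfg.fasta:
        with stage("screen"):
            records = read_fasta(_require(cfg.fasta, "protein FASTA"))
            table = screen_proteome(records, cfg.pattern, cfg.motifs, cfg.motif_order)
            table_path = os.path.join(cfg.out_dir, "candidates.tsv")
            table.to_csv(table_path, sep="\t", index=False)
            manifest["outputs"]["candidates"] = table_path
            blocks = []
            for rec in records:
                hits = scan_architecture(rec, cfg.pattern)
                if not any(h.d44_ok for h in hits):
                    continue
                anns = annotate_motifs(rec, cfg.motifs)
                blocks.append(
                    build_concat_block(rec, anns, cfg.motif_order, hits)
                )
            blocks_path = os.path.join(cfg.out_dir, "concat_blocks.fasta")
            write_blocks_fasta(blocks, blocks_path)
            manifest["outputs"]["blocks"] = blocks_path

    # reconciliation of supplied gene trees
    gene_tree_maps = []
    recs = []
    if cfg.gene_trees:
        if species is None:
            raise PipelineError("gene trees supplied without a species tree", EXIT_SCHEMA)
        with stage("reconcile"):
            for gt_path in cfg.gene_trees:
                gt = read_gene_tree(_require(gt_path, "gene tree"))
                rec = lca_reconcile(gt, species)
                recs.append(rec)
                gene_tree_maps.append(event_map_from_reconciliation(rec))
            recon_path = os.path.join(cfg.out_dir, "reconciliations.json")
            with open(recon_path, "w") as fh:
                json.dump(
                    [
                        {
                            "gene_tree": p,
                            "duplications": r.duplication_count,
                            "losses": r.loss_count,
                            "cost": r.cost,
                        }
                        for p, r in zip(cfg.gene_trees, recs)
                    ],
                    fh,
                    indent=1,
                )
            manifest["outputs"]["reconciliations"] = recon_path

    # copy-number parsimony
    count_map = None
    if cfg.counts:
        if species is None:
            raise PipelineError("counts supplied without a species tree", EXIT_SCHEMA)
        with stage("ancestral"):
            matrix = read_counts_tsv(_require(cfg.counts, "copy-number TSV"))
            acn = ancestral_copy_number(matrix, species, cfg.cost_model)
            count_map = event_map_from_copy_number(acn, species)
            acn_path = os.path.join(cfg.out_dir, "ancestral_states.json")
            with open(acn_path, "w") as fh:
                json.dump(
                    {
                        "states": acn.states,
                        "root_state": acn.root_state,
                        "min_root_states": list(acn.min_root_states),
                        "cost": acn.cost,
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )
            manifest["outputs"]["ancestral_states"] = acn_path

    # synteny + retrocopies
    retro_events = []
    if cfg.gff:
        with stage("synteny"):
            family_map = read_family_map(cfg.family_map) if cfg.family_map else None
            models = _syn.read_gff3(_require(cfg.gff, "GFF3"), family_map=family_map)
            clusters = _syn.detect_clusters(models, window=cfg.window)
            cl_path = os.path.join(cfg.out_dir, "clusters.tsv")
            with open(cl_path, "w") as fh:
                fh.write("scaffold\tmembers\tdiameter\tall_same_strand\n")
                for c in clusters:
                    fh.write(
                        f"{c.scaffold}\t{','.join(g.gene_id for g in c.members)}\t"
                        f"{c.diameter}\t{c.all_same_strand}\n"
                    )
            manifest["outputs"]["clusters"] = cl_path
            by_species: dict = {}
            for m in models:
                by_species.setdefault(m.species, []).append(m)
            calls = []
            for sp in sorted(by_species):
                calls.extend(_syn.classify_retrocopies(by_species[sp]))
            calls_path = os.path.join(cfg.out_dir, "retrocopy_calls.json")
            with open(calls_path, "w") as fh:
                json.dump([vars(c) for c in calls], fh, indent=1)
            manifest["outputs"]["retrocopy_calls"] = calls_path
            if recs:
                for rec in recs:
                    try:
                        retro_events.extend(
                            _syn.assign_retro_events(rec.gene_tree, rec, calls)
                        )
                    except ValueError:
                        log.warning("retro-event assignment skipped: calls do not cover gene tree")

    # combine + report
    with stage("report"):
        if count_map is None and gene_tree_maps:
            count_map = gene_tree_maps[0]
        if count_map is None and species is not None:
            count_map = EventMap.zero(species)
        if count_map is None:
            raise PipelineError(
                "nothing to report: supply counts, gene trees or a species tree",
                EXIT_SCHEMA,
            )
        final = combine_evidence(count_map, gene_tree_maps, cfg.overrides)
        for fmt, fname in (("text", "event_report.txt"), ("json", "event_report.json"),
                           ("tsv", "event_report.tsv")):
            path = os.path.join(cfg.out_dir, fname)
            with open(path, "w") as fh:
                fh.write(render_report(final, retro_events, format=fmt))
            manifest["outputs"][f"report_{fmt}"] = path

    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_counts_tsv(path: str) -> dict:
    """species<TAB>count TSV; count 'NA' (any case) or empty -> missing."""
    out: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or (i == 0 and line.lower().startswith("species")):
                continue
            sp, val = line.split("\t")
            out[sp] = None if val.upper() in ("NA", "") else int(val)
    if not out:
        raise PipelineError(f"no counts in {path}", EXIT_SCHEMA)
    return out


def read_family_map(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, fam = line.split("\t")
            out[gene] = fam
    return out
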