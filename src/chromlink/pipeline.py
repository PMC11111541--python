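"""End-to-end orchestration of the integrative analysis.

Runs the full flow on one study's input files: contact-to-gene
association and cumulative scores, top-fraction ranking, gene-set
resampling enrichment of up/down DEGs, class-level score statistics
(Dunn's test), interaction-distance ECDFs with a KS contrast,
promoter-association proportions, chromatin-state enrichment of genes
and anchors, genome annotation of differential marks, mark-anchor
permutation association, and a signal profile matrix.  Every output file
carries a header with tool version, seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import (
    GeneSet,
    GenomeLayout,
    make_promoters,
    read_bed,
    read_bedgraph,
    read_bedpe_contacts,
    read_gene_table,
)
from .interactions import (
    associate_contacts,
    corresponding_anchors,
    distance_ecdf,
    promoter_association_proportion,
    score_table,
    top_fraction_genes,
)
from .marks import (
    classify_annotation,
    mark_target_association,
    promoter_anchors,
    read_mark_table,
    signal_profile_matrix,
    profile_matrix_frame,
)
from .states import StateSegmentation, enrichment_matrix
from .stats import child_seed, dunn_test, geneset_top_overlap_test, ks_two_sample

log = logging.getLogger("chromlink")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All file paths and parameters for one pipeline run."""

    genes: str
    deg: str
    contacts: str
    layout: str
    outdir: str
    dms_hyper: str | None = None
    dms_hypo: str | None = None
    k27_up: str | None = None
    k27_down: str | None = None
    k9_down: str | None = None
    k9_up: str | None = None
    states: str | None = None
    signal: str | None = None
    q_threshold: float = 0.01
    score_mode: str = "sum_oe"
    top_fraction: float = 0.05
    promoter_upstream: int = 2_000
    promoter_downstream: int = 500
    n_perm_geneset: int = 10_000
    n_perm_region: int = 600
    desert_min_gap: int = 100_000
    profile_body: int = 5_000
    profile_flank: int = 3_000
    profile_bin: int = 50
    seed: int = 1

    def __post_init__(self):
        if self.n_perm_geneset < 100 or self.n_perm_region < 100:
            raise ValueError("permutation counts must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("outdir",):
                continue
            v = getattr(self, f.name)
            if isinstance(v, str) and f.name in (
                "genes", "deg", "contacts", "layout", "dms_hyper", "dms_hypo",
                "k27_up", "k27_down", "k9_down", "k9_up", "states", "signal",
            ) and not Path(v).exists():
                raise FileNotFoundError(f"config entry {f.name}: no such file {v}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"chromlink {__version__}",
        f"seed {config.seed}",
        f"config {config.hash()}",
    ]


def _write_tsv(path, df: pd.DataFrame, config: PipelineConfig, index: bool = False) -> None:
    with open(path, "wt") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_json(path, obj: Any, config: PipelineConfig) -> None:
    payload = {"_meta": {"version": __version__, "seed": config.seed,
                         "config_hash": config.hash()}}
    payload.update(obj)
    with open(path, "wt") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_layout(path) -> GenomeLayout:
    with open(path) as fh:
        data = json.load(fh)
    return GenomeLayout(data["chrom_lengths"], data.get("bin_size", 20_000))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the result objects and writes the bundle."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    stage = "load"
    try:
        layout = load_layout(config.layout)
        genes = read_gene_table(config.genes)
        deg = pd.read_csv(config.deg, sep="\t", comment="#")
        contacts = read_bedpe_contacts(config.contacts, q_threshold=config.q_threshold,
                                       bin_size=layout.bin_size, on_bad_width="keep")
        log.info("loaded %d genes, %d significant contacts", len(genes), len(contacts))
        up_ids = sorted(deg.loc[deg["class"] == "up", "gene_id"])
        down_ids = sorted(deg.loc[deg["class"] == "down", "gene_id"])
        background = sorted(deg["gene_id"])

        stage = "score"
        profiles = associate_contacts(genes, contacts)
        scores = score_table(profiles, mode=config.score_mode)
        ranking = top_fraction_genes(scores, config.top_fraction)
        merged = ranking.table.merge(scores[["gene_id", "n_contacts"]], on="gene_id")
        _write_tsv(outdir / "gene_scores.tsv", merged, config)
        results["scores"] = merged
        results["ranking"] = ranking
        top = sorted(ranking.top_set)

        stage = "geneset_permutation"
        perm = {}
        for name, cand in (("up", up_ids), ("down", down_ids)):
            perm[name] = geneset_top_overlap_test(
                cand, background, top, n_perm=config.n_perm_geneset,
                seed=child_seed(config.seed, f"geneset:{name}"),
            )
            log.info("geneset %s: observed %d, z=%.2f", name, perm[name].observed, perm[name].z)
        _write_json(outdir / "geneset_permutation.json",
                    {k: v.to_dict() for k, v in perm.items()}, config)
        results["geneset_permutation"] = perm

        stage = "class_statistics"
        cls_of = dict(zip(deg["gene_id"], deg["class"]))
        score_by_class = {c: merged.loc[merged["gene_id"].map(cls_of) == c, "score"].to_numpy()
                          for c in ("up", "down", "non")}
        dunn = dunn_test({f"{k}_genes": v for k, v in score_by_class.items() if v.size})
        _write_tsv(outdir / "dunn_scores.tsv", dunn, config)
        results["dunn"] = dunn
        dists = {c: np.concatenate([profiles[g].distances() or [np.nan] for g in ids_])
                 for c, ids_ in (("up", up_ids), ("down", down_ids))}
        dists = {c: v[np.isfinite(v)] for c, v in dists.items()}
        ecdf_frames = []
        for c, v in dists.items():
            if v.size:
                e = distance_ecdf(v)
                e.insert(0, "class", c)
                ecdf_frames.append(e)
        if ecdf_frames:
            _write_tsv(outdir / "distance_ecdf.tsv", pd.concat(ecdf_frames), config)
        if dists["up"].size and dists["down"].size:
            D, p = ks_two_sample(dists["up"], dists["down"])
            results["ks_distance"] = {"D": D, "p": p}
            _write_json(outdir / "ks_distance.json", {"D": D, "p": p}, config)

        stage = "promoter_association"
        promoters = make_promoters(genes, config.promoter_upstream,
                                   config.promoter_downstream, layout)
        prop = {c: promoter_association_proportion(ids_, profiles, promoters)
                for c, ids_ in (("up", up_ids), ("down", down_ids))}
        _write_tsv(outdir / "promoter_association.tsv",
                   pd.DataFrame({"class": list(prop), "proportion": list(prop.values())}),
                   config)
        results["promoter_association"] = prop

        stage = "anchors"
        anchors = {c: corresponding_anchors(ids_, profiles)
                   for c, ids_ in (("up", up_ids), ("down", down_ids))}
        results["anchors"] = anchors

        if config.states:
            stage = "state_enrichment"
            seg = StateSegmentation.from_bed(config.states)
            region_sets = {
                "Up_genes": [genes.by_id[g].interval for g in up_ids],
                "Up_anchors": anchors["up"],
                "Down_genes": [genes.by_id[g].interval for g in down_ids],
                "Down_anchors": anchors["down"],
            }
            region_sets = {k: v for k, v in region_sets.items() if v}
            mat = enrichment_matrix(region_sets, seg, layout)
            _write_tsv(outdir / "state_enrichment_raw.tsv", mat.raw, config, index=True)
            _write_tsv(outdir / "state_enrichment_scaled.tsv", mat.scaled, config, index=True)
            results["state_enrichment"] = mat

        stage = "annotation"
        mark_files = {
            "dms_hyper": (config.dms_hyper, "DMS"),
            "dms_hypo": (config.dms_hypo, "DMS"),
            "k27_up": (config.k27_up, "H3K27me3_peak"),
            "k27_down": (config.k27_down, "H3K27me3_peak"),
            "k9_down": (config.k9_down, "H3K9me3_locus"),
            "k9_up": (config.k9_up, "H3K9me3_locus"),
        }
        marks = {}
        annot_rows = []
        for key, (path, kind) in mark_files.items():
            if path is None:
                continue
            sites = read_mark_table(path, kind)
            marks[key] = sites
            br = classify_annotation(sites, genes, promoters,
                                     desert_min_gap=config.desert_min_gap)
            for cat, n in br.counts.items():
                annot_rows.append((key, cat, n, br.fractions[cat]))
        if annot_rows:
            annot = pd.DataFrame(annot_rows, columns=["mark_set", "category", "count", "fraction"])
            _write_tsv(outdir / "mark_annotation.tsv", annot, config)
            results["annotation"] = annot
        results["marks"] = marks

        stage = "mark_association"
        promoters_by_gene = {p.name: p for p in promoters}
        universe = promoter_anchors(background, profiles, promoters_by_gene)
        assoc = {}
        for key, focal_ids in (("k9_down:up_anchors", up_ids),
                               ("dms_hyper:down_anchors", down_ids)):
            mark_key = key.split(":")[0]
            if mark_key not in marks:
                continue
            targets = promoter_anchors(focal_ids, profiles, promoters_by_gene)
            if not targets or not marks[mark_key]:
                continue
            assoc[key] = mark_target_association(
                marks[mark_key], targets, universe,
                n_perm=config.n_perm_region,
                seed=child_seed(config.seed, f"assoc:{key}"), label=key,
            )
        if assoc:
            _write_json(outdir / "mark_association.json",
                        {k: {s: r.to_dict() for s, r in v.items()} for k, v in assoc.items()},
                        config)
        results["mark_association"] = assoc

        if config.signal:
            stage = "signal_profile"
            signal = read_bedgraph(config.signal)
            focal = [genes.by_id[g] for g in down_ids] or list(genes)
            pm = signal_profile_matrix(
                signal,
                [g.interval for g in focal],
                strands=[g.strand for g in focal],
                body=config.profile_body, flank=config.profile_flank,
                bin_size=config.profile_bin,
            )
            frame = profile_matrix_frame(pm, [g.gene_id for g in focal])
            _write_tsv(outdir / "signal_profile.tsv", frame, config, index=True)
            results["signal_profile"] = pm
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "summary"
    _write_summary(outdir / "summary.md", config, results)
    with open(outdir / "run_log.json", "wt") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "config": dataclasses.asdict(config),
                   "config_hash": config.hash()}, fh, indent=1)
    return results


def _write_summary(path, config: PipelineConfig, results: dict[str, Any]) -> None:
    lines = [
        "# chromlink run summary", "",
        f"- version: {__version__}",
        f"- seed: {config.seed}",
        f"- config hash: {config.hash()}", "",
    ]
    perm = results.get("geneset_permutation", {})
    for name, r in perm.items():
        lines.append(
            f"- {name}-genes vs top {config.top_fraction:.0%} scored genes: "
            f"observed overlap {r.observed:.0f}, z={r.z:.2f}, "
            f"p_greater={r.p_greater:.4g}, p_less={r.p_less:.4g}"
        )
    prop = results.get("promoter_association", {})
    for name, v in prop.items():
        lines.append(f"- promoter-associated contact proportion ({name}-genes): {v:.1%}")
    ks = results.get("ks_distance")
    if ks:
        lines.append(f"- KS up-vs-down contact distance: D={ks['D']:.3f}, p={ks['p']:.3g}")
    for key, res in results.get("mark_association", {}).items():
        for stat, r in res.items():
            lines.append(f"- {key} [{stat}]: observed={r.observed:.1f}, z={r.z:.2f}, "
                         f"p_less={r.p_less:.4g}, p_greater={r.p_greater:.4g}")
    with open(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")
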