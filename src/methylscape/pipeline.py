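"""End-to-end pipeline: simulate -> call -> merge -> DMR -> annotate ->
metaplot -> report -> associate -> compare.

Every intermediate is written as plain text (FASTA/GFF3/TSV/BED) so each
stage can be re-run and inspected independently; a ``manifest.json``
records the full parameter set and the SHA-256 of every output file, so
two runs of the same config can be compared byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as msio
from .annotation import FeatureIndex, write_gff3
from .calling import MethylationCallingModel, merge_replicates
from .dmr import DmrModel
from .expression import (
    associate_dmr_deg,
    compare_time_points,
    filter_degs,
    methdeg_crosstab,
)
from .profiles import context_proportions, global_levels, metaplot, region_proportions
from .simulate import (
    CONTROL_LABEL,
    SimulationConfig,
    simulate_annotation,
    simulate_bisulfite_counts,
    simulate_expression,
    simulate_genome,
)

logger = logging.getLogger("methylscape")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    ``conditions`` are the treatment labels compared against the control;
    each gets its own DMR comparison, expression table and methDEG set.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    conditions: list[str] = field(default_factory=lambda: ["t4h", "t14h"])
    contexts: list[str] = field(default_factory=lambda: ["CG", "CHG", "CHH"])
    fdr: float = 0.01
    min_coverage: int = 10
    window: int = 200
    step: int = 200
    min_sites: int = 5
    min_fold: float = 2.0
    p_threshold: float = 1e-20
    flank: int = 2000
    metaplot_window: int = 50
    metaplot_step: int = 50
    body_bins: int = 40
    upstream_window: int = 2000
    deg_min_fold: float = 2.0
    deg_max_q: float = 0.01

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        return cls(sim=SimulationConfig.from_dict(sim), **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_all(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full pipeline into ``outdir`` and return a result bundle.

    The bundle maps stage names to in-memory results; the on-disk outputs
    plus ``manifest.json`` are the authoritative record.  ``seed``
    overrides ``config.sim.seed`` when given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = RunConfig.from_dict({**config.to_dict(), "sim": {**config.sim.to_dict(), "seed": seed}})
    sim = config.sim
    bundle: dict = {"config": config}

    logger.info("stage simulate: genome + annotation")
    genome = simulate_genome(sim)
    msio.write_fasta(genome, outdir / "genome.fa")
    annotation = simulate_annotation(sim, genome)
    write_gff3(annotation, outdir / "annotation.gff3")
    index = FeatureIndex.from_gff3(
        outdir / "annotation.gff3",
        upstream_bp=config.upstream_window,
        downstream_bp=config.upstream_window,
    )
    bundle["genome"] = genome
    bundle["index"] = index

    all_conditions = [CONTROL_LABEL] + list(config.conditions)
    truth = None
    merged = {}
    for cond in all_conditions:
        logger.info("stage simulate+call: condition %s", cond)
        tables, truth = simulate_bisulfite_counts(sim, genome, annotation, cond)
        reps = []
        for i, tbl in enumerate(tables, start=1):
            msio.write_counts(tbl, outdir / f"counts_{cond}_rep{i}.tsv")
            model = MethylationCallingModel(
                tbl, spike_in_name=sim.spike_in_name,
                sample_id=f"{cond}_rep{i}", condition=cond,
            )
            res = model.fit(fdr=config.fdr)
            msio.write_calls(res.calls, outdir / f"calls_{cond}_rep{i}.tsv")
            reps.append(res)
        m = merge_replicates(reps[0], reps[1], min_coverage=config.min_coverage)
        msio.write_calls(m.calls, outdir / f"calls_{cond}_merged.tsv")
        merged[cond] = m
    bundle["calls"] = merged

    expr = {}
    for cond in config.conditions:
        tbl = simulate_expression(sim, annotation, truth, condition_label=cond)
        msio.write_expression(tbl, outdir / f"expression_{cond}.tsv")
        expr[cond] = tbl
    truth.write(outdir / "truth")
    bundle["truth"] = truth

    logger.info("stage dmr")
    dmr_results = {}
    for cond in config.conditions:
        for ctx in config.contexts:
            model = DmrModel(
                merged[CONTROL_LABEL], merged[cond], ctx,
                window_size=config.window, step=config.step,
                min_sites=config.min_sites, min_fold=config.min_fold,
                p_threshold=config.p_threshold,
                chrom_lengths=index.chrom_lengths,
            )
            res = model.fit()
            res.assign_categories(index)
            res.to_bed(outdir / f"dmrs_{cond}_{ctx}.bed")
            dmr_results[(cond, ctx)] = res
    bundle["dmrs"] = dmr_results

    logger.info("stage report + metaplot")
    control = merged[CONTROL_LABEL]
    levels = global_levels(control)
    levels.to_csv(outdir / "report_global_levels.tsv", sep="\t", index=False)
    ctx_report = context_proportions(control)
    ctx_report.table.to_csv(outdir / "report_context_proportions.tsv", sep="\t", index=False)
    mc = control.mc_sites.copy()
    mc["category"] = index.mc_categories(mc)
    region_report = region_proportions(mc)
    region_report.table.to_csv(outdir / "report_region_proportions.tsv", sep="\t", index=False)
    for cls in ("gene", "te"):
        prof = metaplot(
            control, index, feature_class=cls, flank=config.flank,
            window=config.metaplot_window, step=config.metaplot_step,
            body_bins=config.body_bins,
        )
        prof.table.to_csv(outdir / f"metaplot_{cls}.tsv", sep="\t", index=False,
                          float_format="%.6g")
    bundle["reports"] = {"levels": levels, "context": ctx_report, "region": region_report}

    logger.info("stage associate + compare")
    methdegs = {}
    for cond in config.conditions:
        degs = filter_degs(expr[cond], min_fold=config.deg_min_fold, max_q=config.deg_max_q)
        degs.to_csv(outdir / f"degs_{cond}.tsv", sep="\t", index=False)
        dmr_frames = [
            dmr_results[(cond, ctx)].dmrs
            for ctx in config.contexts
            if len(dmr_results[(cond, ctx)].dmrs)
        ]
        all_dmrs = (
            pd.concat(dmr_frames, ignore_index=True)
            if dmr_frames
            else pd.DataFrame(columns=["chrom", "start", "end", "context", "direction"])
        )
        md = associate_dmr_deg(all_dmrs, degs, index,
                               upstream_window=config.upstream_window, condition=cond)
        md.to_csv(outdir / f"methdegs_{cond}.tsv", sep="\t", index=False)
        methdeg_crosstab(md).to_csv(outdir / f"methdegs_{cond}_crosstab.tsv",
                                    sep="\t", index=False)
        methdegs[cond] = md
    bundle["methdegs"] = methdegs

    if len(config.conditions) >= 2:
        c1, c2 = config.conditions[:2]
        comp = compare_time_points(methdegs[c1], methdegs[c2])
        rows = [(k, ",".join(sorted(v))) for k, v in comp.items()]
        pd.DataFrame(rows, columns=["set", "gene_ids"]).to_csv(
            outdir / "methdeg_comparison.tsv", sep="\t", index=False
        )
        bundle["comparison"] = comp

    manifest = {
        "config": config.to_dict(),
        "files": {
            p.name: msio.sha256_file(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
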