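"""Synthetic WGBS study generator with planted truth.

Generates a toy genome plus an unmethylated lambda spike-in, a gene/TE
annotation, per-cytosine bisulfite count tables for two replicates of each
condition, and a per-gene expression table — all with a
:class:`TruthTable` recording the planted differentially methylated windows,
the planted differentially expressed genes, and the DMR-to-gene links, so
every downstream stage can be scored against known truth.

The observation model per cytosine site is

    n ~ Poisson(mean_coverage),   k ~ Binomial(n, m + (1 - m) * e)

where ``m`` is the site's true methylation level and ``e`` the bisulfite
nonconversion-plus-sequencing error rate.  True levels are drawn once per
site from a context-specific beta distribution and shared across conditions
and replicates; the treatment condition differs from control only inside
planted DMR windows, where the level is multiplied (hyper) or divided
(hypo) by ``dmr_effect`` and clamped to [0, 1].  Spike-in cytosines have
``m = 0`` everywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import Annotation, FeatureIndex, Gene, Transposon
from .contexts import CONTEXTS, find_cytosines

CONTROL_LABEL = "control"

#: distinct rng stream codes per generation stage
_RNG_GENOME, _RNG_ANNOT, _RNG_LEVELS, _RNG_TRUTH, _RNG_COUNTS, _RNG_EXPR = range(6)


def _cond_code(label: str) -> int:
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions of a plant heat-stress WGBS
    experiment at toy genome scale: ~30x coverage, a 0.5% error rate, and
    context mean methylation levels CG 0.393, CHG 0.1538, CHH 0.0524.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    gc_fraction: float = 0.36
    n_genes: int = 24
    n_tes: int = 16
    mean_coverage: float = 30.0
    nonconversion_rate: float = 0.005
    context_level_means: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.393, "CHG": 0.1538, "CHH": 0.0524}
    )
    level_dispersion: float = 0.5
    n_planted_dmrs: int = 12
    dmr_effect: float = 4.0
    n_planted_degs: int = 12
    deg_log2fc: float = 2.0
    frac_degs_with_dmr: float = 0.5
    # generator plumbing
    spike_in_name: str = "lambda"
    spike_in_length: int = 48_502
    dmr_context: str = "CG"
    dmr_directions: tuple = ("hyper", "hypo")
    dmr_window_bp: int = 200
    frac_silent_genes: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "nonconversion_rate", "frac_degs_with_dmr",
                     "frac_silent_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ctx, m in self.context_level_means.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"context mean for {ctx} must be in [0, 1], got {m}")
        if self.dmr_effect < 1.0:
            raise ValueError("dmr_effect must be >= 1")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.chrom_length <= 0 or self.spike_in_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if self.deg_log2fc < 1.0:
            raise ValueError("deg_log2fc must be >= 1 so planted DEGs pass the 2-fold filter")
        if self.dmr_context not in CONTEXTS:
            raise ValueError(f"dmr_context must be one of {CONTEXTS}")
        self.dmr_directions = tuple(self.dmr_directions)
        if not self.dmr_directions or not set(self.dmr_directions) <= {"hyper", "hypo"}:
            raise ValueError("dmr_directions must be a non-empty subset of hyper/hypo")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dmr_directions"] = list(d["dmr_directions"])  # YAML-safe
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class TruthTable:
    """Planted truth of one synthetic study.

    ``planted_dmrs`` holds (chrom, start, end, context, direction) with
    0-based half-open coordinates; ``planted_degs`` maps a treatment
    condition label to its (gene_id, direction) list; ``dmr_to_gene_links``
    holds (chrom, start, end, gene_id, region) with region ``upstream`` or
    ``body``.
    """

    planted_dmrs: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    planted_degs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    dmr_to_gene_links: list[tuple[str, int, int, str, str]] = field(default_factory=list)

    def deg_ids(self, condition: str) -> set[str]:
        return {g for g, _ in self.planted_degs.get(condition, [])}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.planted_dmrs, columns=["chrom", "start", "end", "context", "direction"]
        ).to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
        rows = [
            (cond, g, d) for cond, lst in sorted(self.planted_degs.items()) for g, d in lst
        ]
        pd.DataFrame(rows, columns=["condition", "gene_id", "direction"]).to_csv(
            outdir / "truth_degs.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            self.dmr_to_gene_links, columns=["chrom", "start", "end", "gene_id", "region"]
        ).to_csv(outdir / "truth_links.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthTable":
        outdir = Path(outdir)
        dmrs = pd.read_csv(outdir / "truth_dmrs.tsv", sep="\t")
        degs = pd.read_csv(outdir / "truth_degs.tsv", sep="\t")
        links = pd.read_csv(outdir / "truth_links.tsv", sep="\t")
        planted_degs: dict[str, list[tuple[str, str]]] = {}
        for cond, sub in degs.groupby("condition", sort=True):
            planted_degs[str(cond)] = list(
                zip(sub["gene_id"].astype(str), sub["direction"].astype(str))
            )
        return cls(
            planted_dmrs=[tuple(r) for r in dmrs.itertuples(index=False)],
            planted_degs=planted_degs,
            dmr_to_gene_links=[tuple(r) for r in links.itertuples(index=False)],
        )


# ----------------------------------------------------------------------
# genome
# ----------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random chromosomes at the configured GC fraction plus the spike-in.

    Returns an ordered mapping chromosome name -> sequence; the last entry
    is the fully unmethylated spike-in (named ``lambda`` by default), which
    downstream stages exclude from genome-wide statistics by name.
    """
    rng = np.random.default_rng([config.seed, _RNG_GENOME])
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(bases, size=config.chrom_length, p=probs)
        genome[f"chr{i + 1}"] = "".join(seq)
    spike = rng.choice(bases, size=config.spike_in_length, p=probs)
    genome[config.spike_in_name] = "".join(spike)
    return genome


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, genome: Mapping[str, str]) -> Annotation:
    """Place non-overlapping gene models and intergenic TEs on the genome.

    Genes get 1-5 exons with derived introns; TEs are placed in the gaps
    between genes.  Raises if the requested feature count does not fit.
    """
    rng = np.random.default_rng([config.seed, _RNG_ANNOT])
    chroms = [c for c in genome if c != config.spike_in_name]
    chrom_lengths = {c: len(genome[c]) for c in chroms}

    genes: list[Gene] = []
    gaps: list[tuple[str, int, int]] = []  # intergenic space left for TEs
    per_chrom = np.zeros(len(chroms), dtype=int)
    for i in range(config.n_genes):
        per_chrom[i % len(chroms)] += 1

    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        L = chrom_lengths[chrom]
        cursor = int(rng.integers(500, 2000))
        for _ in range(n_here):
            glen = int(rng.integers(1200, 3501))
            if cursor + glen + 500 > L:
                raise ValueError(
                    f"insufficient space on {chrom} for {config.n_genes} genes"
                )
            start, end = cursor, cursor + glen
            gid += 1
            genes.append(
                Gene(f"gene{gid:04d}", chrom, start, end,
                     str(rng.choice(["+", "-"])), _make_exons(rng, start, end))
            )
            gap = int(rng.integers(2500, 3501))
            gaps.append((chrom, end + 100, min(end + gap - 100, L)))
            cursor = end + gap
        if cursor < L:
            gaps.append((chrom, cursor, L))

    tes: list[Transposon] = []
    usable = [g for g in gaps if g[2] - g[1] >= 400]
    if not usable and config.n_tes > 0:
        raise ValueError("insufficient intergenic space for TEs")
    for i in range(config.n_tes):
        for _attempt in range(200):
            chrom, gs, ge = usable[int(rng.integers(len(usable)))]
            tlen = int(rng.integers(300, min(1501, ge - gs + 1)))
            if ge - gs < tlen:
                continue
            ts = int(rng.integers(gs, ge - tlen + 1))
            if any(t.chrom == chrom and ts < t.end and t.start < ts + tlen for t in tes):
                continue
            tes.append(Transposon(f"te{i + 1:04d}", chrom, ts, ts + tlen,
                                  str(rng.choice(["+", "-"]))))
            break
        else:
            raise ValueError("insufficient intergenic space for requested TE count")
    return Annotation(chrom_lengths, genes, tes)


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    span = end - start
    n_ex = int(rng.integers(1, 6))
    n_parts = 2 * n_ex - 1
    min_part = 60
    if span < n_parts * min_part:
        n_ex = max(1, span // (2 * min_part))
        n_parts = 2 * n_ex - 1
    w = rng.random(n_parts) + 0.25
    lengths = np.floor(w / w.sum() * (span - n_parts * min_part)).astype(int) + min_part
    lengths[-1] += span - lengths.sum()
    bounds = np.concatenate([[start], start + np.cumsum(lengths)])
    return [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]


# ----------------------------------------------------------------------
# per-site truth and bisulfite counts
# ----------------------------------------------------------------------

def _cytosine_sites(genome: Mapping[str, str]) -> dict[str, pd.DataFrame]:
    return {chrom: find_cytosines(seq) for chrom, seq in genome.items()}


def _baseline_levels(config: SimulationConfig,
                     sites: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Per-site true levels drawn once, shared by all conditions/replicates."""
    rng = np.random.default_rng([config.seed, _RNG_LEVELS])
    kappa = config.level_dispersion
    levels: dict[str, np.ndarray] = {}
    for chrom, df in sites.items():
        m = np.zeros(len(df))
        if chrom == config.spike_in_name:
            levels[chrom] = m
            continue
        for ctx in CONTEXTS:
            mask = (df["context"] == ctx).to_numpy()
            mu = config.context_level_means.get(ctx, 0.0)
            if mu <= 0.0:
                continue
            if mu >= 1.0:
                m[mask] = 1.0
            else:
                m[mask] = rng.beta(mu * kappa, (1 - mu) * kappa, size=mask.sum())
        levels[chrom] = m
    return levels


def plant_dmr_truth(
    config: SimulationConfig,
    sites: dict[str, pd.DataFrame],
    annotation: Annotation,
) -> tuple[TruthTable, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Choose planted DMR windows and build control/treatment level overrides.

    Windows are tiles of ``dmr_window_bp`` with at least 8 sites of the
    planted context; half are drawn from tiles overlapping gene bodies or
    their 2-kb upstream windows so that DMR-to-gene links exist.  Adjacent
    tiles are never both planted.  Inside a planted window, control levels
    are drawn tightly around the context mean and the treatment level is the
    control level scaled by ``dmr_effect`` (hyper) or its inverse (hypo).

    Returns the truth table and two per-chromosome override arrays
    (control, treatment); NaN entries mean "use the shared baseline".
    """
    rng = np.random.default_rng([config.seed, _RNG_TRUTH])
    ctx = config.dmr_context
    win = config.dmr_window_bp
    index = FeatureIndex(annotation)

    # eligible tiles per chromosome
    eligible: list[tuple[str, int]] = []
    site_pos: dict[str, np.ndarray] = {}
    for chrom, df in sites.items():
        if chrom == config.spike_in_name:
            continue
        pos0 = df.loc[df["context"] == ctx, "pos"].to_numpy() - 1
        site_pos[chrom] = pos0
        n_tiles = annotation.chrom_lengths[chrom] // win
        counts = np.bincount(pos0 // win, minlength=n_tiles)[:n_tiles]
        for t in np.flatnonzero(counts >= 8):
            eligible.append((chrom, int(t)))

    linked = [
        (chrom, t)
        for chrom, t in eligible
        if index.genes_overlapping(chrom, t * win, (t + 1) * win, "gene_body")
        or index.genes_overlapping(chrom, t * win, (t + 1) * win, "upstream")
    ]
    unlinked = [x for x in eligible if x not in set(linked)]

    n_want = config.n_planted_dmrs
    n_linked = min(len(linked), (n_want + 1) // 2)
    chosen: list[tuple[str, int]] = []
    taken: set[tuple[str, int]] = set()

    def _pick(pool: list[tuple[str, int]], k: int) -> None:
        if k <= 0 or not pool:
            return
        order = rng.permutation(len(pool))
        for j in order:
            chrom, t = pool[j]
            if (chrom, t) in taken or (chrom, t - 1) in taken or (chrom, t + 1) in taken:
                continue
            chosen.append((chrom, t))
            taken.add((chrom, t))
            k -= 1
            if k == 0:
                break

    _pick(linked, n_linked)
    _pick([x for x in unlinked if x not in taken], n_want - len(chosen))
    if len(chosen) < n_want:
        raise ValueError(
            f"only {len(chosen)} of {n_want} planted DMR windows could be placed; "
            "increase genome size or lower n_planted_dmrs"
        )

    mu = config.context_level_means[ctx]
    truth = TruthTable()
    ctrl_over = {c: np.full(len(df), np.nan) for c, df in sites.items()}
    trt_over = {c: np.full(len(df), np.nan) for c, df in sites.items()}
    for chrom, t in sorted(chosen):
        start, end = t * win, (t + 1) * win
        direction = str(rng.choice(list(config.dmr_directions)))
        df = sites[chrom]
        in_win = (
            (df["context"] == ctx)
            & (df["pos"] - 1 >= start)
            & (df["pos"] - 1 < end)
        ).to_numpy()
        base = rng.beta(mu * 50, (1 - mu) * 50, size=in_win.sum())
        if direction == "hyper":
            shifted = np.clip(base * config.dmr_effect, 0.0, 1.0)
        else:
            shifted = base / config.dmr_effect
        ctrl_over[chrom][in_win] = base
        trt_over[chrom][in_win] = shifted
        truth.planted_dmrs.append((chrom, start, end, ctx, direction))
        for region, kind in (("body", "gene_body"), ("upstream", "upstream")):
            for g in index.genes_overlapping(chrom, start, end, kind):
                truth.dmr_to_gene_links.append((chrom, start, end, g, region))
    return truth, ctrl_over, trt_over


def simulate_bisulfite_counts(
    config: SimulationConfig,
    genome: Mapping[str, str],
    annotation: Annotation,
    condition_label: str,
    n_replicates: int = 2,
) -> tuple[list[pd.DataFrame], TruthTable]:
    """Per-cytosine count tables for one condition plus the planted truth.

    Any ``condition_label`` other than ``"control"`` receives the planted
    DMR level shifts.  Returns ``n_replicates`` tables with columns
    ``chrom pos strand context meth_reads total_reads`` (pos 1-based; rows
    with zero coverage dropped) and the :class:`TruthTable`, which is
    identical for every condition of the same config.
    """
    sites = _cytosine_sites(genome)
    base = _baseline_levels(config, sites)
    truth, ctrl_over, trt_over = plant_dmr_truth(config, sites, annotation)
    over = ctrl_over if condition_label == CONTROL_LABEL else trt_over

    e = config.nonconversion_rate
    tables: list[pd.DataFrame] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            [config.seed, _RNG_COUNTS, _cond_code(condition_label), rep]
        )
        frames = []
        for chrom, df in sites.items():
            m = np.where(np.isnan(over[chrom]), base[chrom], over[chrom])
            n = rng.poisson(config.mean_coverage, size=len(df))
            p_obs = m + (1.0 - m) * e
            k = rng.binomial(n, p_obs)
            keep = n > 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": df["pos"].to_numpy()[keep],
                        "strand": df["strand"].to_numpy()[keep],
                        "context": df["context"].to_numpy()[keep],
                        "meth_reads": k[keep],
                        "total_reads": n[keep],
                    }
                )
            )
        tables.append(pd.concat(frames, ignore_index=True))
    return tables, truth


# ----------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    annotation: Annotation,
    truth: TruthTable,
    condition_label: str = "treatment",
) -> pd.DataFrame:
    """Per-gene RPKM table for one treatment-vs-control comparison.

    Planted DEGs get ``|log2FC| >= deg_log2fc`` and Q-values below the
    downstream DEG filter (Q <= 0.01); all other genes are constructed to
    fail it.  A fraction ``frac_degs_with_dmr`` of planted DEGs is drawn
    from genes linked to planted DMR windows in the truth table; the
    selection is recorded in ``truth.planted_degs[condition_label]``.

    Columns: ``gene_id rpkm_ctrl rpkm_trt fold_change q_value`` where
    ``fold_change`` is the linear ratio treatment/control.
    """
    rng = np.random.default_rng(
        [config.seed, _RNG_EXPR, _cond_code(condition_label)]
    )
    gene_ids = [g.gene_id for g in annotation.genes]
    n = len(gene_ids)
    if config.n_planted_degs > n:
        raise ValueError("n_planted_degs exceeds gene count")

    linked_pool = sorted(
        {g for *_ , g, _region in truth.dmr_to_gene_links if g in set(gene_ids)}
    )
    n_linked = int(round(config.frac_degs_with_dmr * config.n_planted_degs))
    if n_linked > len(linked_pool):
        raise ValueError(
            f"frac_degs_with_dmr requires {n_linked} DMR-linked genes "
            f"but only {len(linked_pool)} exist; plant more DMRs"
        )
    picked_linked = list(
        np.array(linked_pool, dtype=object)[
            rng.permutation(len(linked_pool))[:n_linked]
        ]
    )
    rest_pool = [g for g in gene_ids if g not in set(picked_linked)]
    picked_rest = list(
        np.array(rest_pool, dtype=object)[
            rng.permutation(len(rest_pool))[: config.n_planted_degs - n_linked]
        ]
    )
    planted = picked_linked + picked_rest
    planted_set = set(planted)

    silent_pool = [g for g in gene_ids if g not in planted_set]
    n_silent = int(round(config.frac_silent_genes * n))
    silent = set(
        np.array(silent_pool, dtype=object)[
            rng.permutation(len(silent_pool))[:n_silent]
        ]
    ) if silent_pool else set()

    rows = []
    degs: list[tuple[str, str]] = []
    for g in gene_ids:
        if g in silent:
            rows.append((g, 0.0, 0.0, np.nan, 1.0))
            continue
        base = float(np.exp(rng.normal(1.0, 1.2)))
        if g in planted_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * (config.deg_log2fc + abs(rng.normal(0.0, 0.3)))
            q = float(10.0 ** rng.uniform(-8, -3))
            degs.append((g, "up" if sign > 0 else "down"))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.25), -0.9, 0.9))
            q = float(rng.uniform(0.02, 1.0))
        trt = base * 2.0 ** lfc
        rows.append((g, round(base, 4), round(trt, 4), round(2.0 ** lfc, 4), q))
    truth.planted_degs[condition_label] = degs
    return pd.DataFrame(
        rows, columns=["gene_id", "rpkm_ctrl", "rpkm_trt", "fold_change", "q_value"]
    )
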