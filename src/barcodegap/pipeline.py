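"""Full barcode-candidate evaluation pipeline over one or more regions.

``run`` executes, per region: alignment summary statistics -> K2P distance
matrix -> intra/inter partition, gap report and histograms -> BM/BCM/ASB
identification summaries -> NJ tree with bootstrap supports -> monophyly
scoring; and additionally evaluates the concatenation of two regions sharing
record ids.  Every number in the report is recomputable by calling the
underlying module functions on the same inputs — the pipeline adds no
arithmetic of its own.

Output artifacts are plain TSV/JSON (plus Newick trees); no timestamps are
written, so runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignedMatrix, concatenate, read_alignment, read_species_map
from .distance import DistanceMatrix, distance_matrix
from .gap import DistancePartition, GapReport, HistogramTable, gap_report, histogram, partition
from .identify import (
    IdentificationResult,
    IdentificationSummary,
    bcm_threshold,
    evaluate,
    results_table,
    summary_table,
)
from .stats import AlignmentSummary, summarize
from .tree import BootstrapInfo, bootstrap, monophyly, MonophylyReport, newick_string, read_newick

__all__ = ["PipelineConfig", "RegionReport", "RunReport", "evaluate_region", "run", "compare_regions"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one evaluation run.

    Every analysis knob has an explicit field: the BCM percentile, the
    distance-tie tolerance, both histogram bin widths, and the bootstrap
    replicate count.  A seed is required whenever ``bootstrap_reps > 0``.
    """

    inputs: dict[str, str]  # region -> aligned FASTA path
    species_map_path: str | None = None
    bcm_percentile: float = 0.95
    tie_tolerance: float = 1e-10
    histogram_bin_widths: tuple[float, ...] = (0.005, 0.05)
    bootstrap_reps: int = 1000
    seed: int | None = None
    singleton_policy: str = "discriminated"
    concatenate_regions: bool = True
    external_trees: dict[str, str] = field(default_factory=dict)
    output_dir: str | None = None

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("no input alignments configured")
        for region, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{region}: alignment not found: {path}")
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("a seed is required when bootstrap_reps > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "histogram_bin_widths" in data:
            data["histogram_bin_widths"] = tuple(data["histogram_bin_widths"])
        return cls(**data)


@dataclass
class RegionReport:
    """All per-region results."""

    region: str
    alignment_summary: AlignmentSummary
    gap: GapReport
    histograms: dict[float, HistogramTable]
    bcm_threshold: float | None
    identification: dict[str, IdentificationSummary]
    identification_results: dict[str, list[IdentificationResult]]
    monophyly: MonophylyReport | None
    external_monophyly: MonophylyReport | None
    bootstrap_info: BootstrapInfo | None
    n_undefined_pairs: int
    species_of: dict[str, str] = field(default_factory=dict)
    tree_newick: str | None = None


@dataclass
class RunReport:
    regions: dict[str, RegionReport]
    config: PipelineConfig
    warnings: list[str] = field(default_factory=list)
    version: str = __version__


def evaluate_region(
    m: AlignedMatrix,
    bcm_percentile: float = 0.95,
    tie_tolerance: float = 1e-10,
    histogram_bin_widths: tuple[float, ...] = (0.005, 0.05),
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    singleton_policy: str = "discriminated",
    external_tree_path: str | None = None,
) -> RegionReport:
    """Run every evaluation stage on a single region matrix."""
    summary = summarize(m)
    dm = distance_matrix(m)
    part = partition(dm)
    gap = gap_report(part)
    hists = {w: histogram(part, w) for w in histogram_bin_widths}

    ident: dict[str, IdentificationSummary] = {}
    ident_results: dict[str, list[IdentificationResult]] = {}
    thr: float | None
    try:
        thr = bcm_threshold(part, bcm_percentile)
    except ValueError:
        thr = None
        logger.warning("%s: no intraspecific distances; BCM skipped", m.region)
    for method in ("BM", "ASB"):
        s, r = evaluate(dm, method, tol=tie_tolerance)
        ident[method], ident_results[method] = s, r
    if thr is not None:
        s, r = evaluate(dm, "BCM", threshold=thr, tol=tie_tolerance)
        ident["BCM"], ident_results["BCM"] = s, r

    species_of = dict(zip(dm.ids, dm.species))
    mono = boot_info = None
    newick = None
    if dm.n_undefined_pairs == 0 and dm.n >= 3:
        tree, boot_info = bootstrap(m, n_reps=bootstrap_reps, seed=seed)
        mono = monophyly(tree, species_of, singleton_policy=singleton_policy)
        newick = newick_string(tree)
    else:
        logger.warning(
            "%s: tree stage skipped (undefined distances or <3 records)", m.region
        )

    ext_mono = None
    if external_tree_path:
        ext_tree = read_newick(external_tree_path, expected_ids=set(dm.ids))
        ext_mono = monophyly(ext_tree, species_of, singleton_policy=singleton_policy)

    return RegionReport(
        region=m.region,
        alignment_summary=summary,
        gap=gap,
        histograms=hists,
        bcm_threshold=thr,
        identification=ident,
        identification_results=ident_results,
        monophyly=mono,
        external_monophyly=ext_mono,
        bootstrap_info=boot_info,
        n_undefined_pairs=dm.n_undefined_pairs,
        species_of=species_of,
        tree_newick=newick,
    )


def run(cfg: PipelineConfig) -> RunReport:
    """Execute the full pipeline per configured region (plus concatenation).

    When exactly two regions are configured and share all record ids, their
    concatenation is evaluated as an additional region.  Artifacts are
    written under ``cfg.output_dir`` when set.
    """
    cfg.validate()
    species_map = (
        read_species_map(cfg.species_map_path) if cfg.species_map_path else None
    )
    matrices: dict[str, AlignedMatrix] = {}
    for region, path in cfg.inputs.items():
        matrices[region] = read_alignment(path, species_map=species_map, region=region)

    if cfg.concatenate_regions and len(matrices) == 2:
        (r1, m1), (r2, m2) = sorted(matrices.items())
        if set(m1.ids) == set(m2.ids):
            joined = concatenate(m1, m2)
            matrices[joined.region] = joined
        else:
            logger.warning(
                "regions %s and %s do not share record ids; concatenation skipped",
                r1,
                r2,
            )

    regions: dict[str, RegionReport] = {}
    warnings: list[str] = []
    for region, m in matrices.items():
        rep = evaluate_region(
            m,
            bcm_percentile=cfg.bcm_percentile,
            tie_tolerance=cfg.tie_tolerance,
            histogram_bin_widths=cfg.histogram_bin_widths,
            bootstrap_reps=cfg.bootstrap_reps,
            seed=cfg.seed,
            singleton_policy=cfg.singleton_policy,
            external_tree_path=cfg.external_trees.get(region),
        )
        regions[region] = rep
        if rep.n_undefined_pairs:
            warnings.append(f"{region}: {rep.n_undefined_pairs} undefined distance pairs")
        if rep.bootstrap_info and rep.bootstrap_info.n_skipped:
            warnings.append(
                f"{region}: {rep.bootstrap_info.n_skipped} bootstrap replicates skipped"
            )
        if rep.gap.singletons:
            warnings.append(f"{region}: singleton species {rep.gap.singletons}")

    report = RunReport(regions=regions, config=cfg, warnings=warnings)
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def write_report(report: RunReport, output_dir: str | Path) -> None:
    """Write all TSV/JSON/Newick artifacts plus a JSON run report."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "region": r.region,
                **asdict(r.alignment_summary),
                "variable_sites_pct": round(100 * r.alignment_summary.variable_fraction, 2),
                "parsimony_sites_pct": round(100 * r.alignment_summary.parsimony_fraction, 2),
            }
            for r in report.regions.values()
        ]
    ).to_csv(out / "alignment_summary.tsv", sep="\t", index=False)

    id_rows = []
    for r in report.regions.values():
        for method, s in r.identification.items():
            id_rows.append({"region": r.region, **s.as_row()})
    pd.DataFrame(id_rows).to_csv(out / "identification_summary.tsv", sep="\t", index=False)

    for r in report.regions.values():
        tag = r.region.replace("+", "plus").replace("/", "_")
        for w, h in r.histograms.items():
            h.to_dataframe().to_csv(
                out / f"histogram_{tag}_w{w:g}.tsv", sep="\t", index=False
            )
        with open(out / f"gap_report_{tag}.json", "w") as fh:
            json.dump(r.gap.to_dict(), fh, indent=2, sort_keys=True)
        all_results = [res for rs in r.identification_results.values() for res in rs]
        results_table(all_results, r.species_of).to_csv(
            out / f"identification_results_{tag}.tsv", sep="\t", index=False
        )
        if r.monophyly:
            with open(out / f"monophyly_{tag}.json", "w") as fh:
                json.dump(r.monophyly.to_dict(), fh, indent=2, sort_keys=True)
        if r.tree_newick:
            (out / f"nj_tree_{tag}.nwk").write_text(r.tree_newick)

    config_echo = asdict(report.config)
    config_echo.pop("output_dir", None)  # keep reports byte-comparable across dirs
    provenance = {
        "version": report.version,
        "config": config_echo,
        "warnings": report.warnings,
        "regions": {
            name: {
                "bcm_threshold": r.bcm_threshold,
                "n_undefined_pairs": r.n_undefined_pairs,
                "bootstrap": asdict(r.bootstrap_info) if r.bootstrap_info else None,
                "monophyly_rates": (
                    {
                        "individuals": r.monophyly.discrimination_rate_individuals,
                        "species": r.monophyly.discrimination_rate_species,
                    }
                    if r.monophyly
                    else None
                ),
            }
            for name, r in report.regions.items()
        },
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)


def compare_regions(report: RunReport, metric: str = "BM") -> pd.DataFrame:
    """Rank regions by identification success (default: BM correct %).

    One row per region x method; regions are ordered by the chosen method's
    correct percentage, ties broken lexicographically by region name.
    """
    if len(report.regions) < 2:
        raise ValueError("compare_regions needs at least 2 regions")
    rows = []
    for name, r in report.regions.items():
        for method, s in r.identification.items():
            rows.append(
                {
                    "region": name,
                    "method": method,
                    "correct_pct": round(s.pct_correct, 2),
                    "ambiguous_pct": round(s.pct_ambiguous, 2),
                    "incorrect_pct": round(s.pct_incorrect, 2),
                    "no_match_pct": round(s.pct_no_match, 2),
                }
            )
        if r.monophyly:
            rows.append(
                {
                    "region": name,
                    "method": "NJ-monophyly",
                    "correct_pct": round(100 * r.monophyly.discrimination_rate_individuals, 2),
                    "ambiguous_pct": 0.0,
                    "incorrect_pct": round(
                        100 * (1 - r.monophyly.discrimination_rate_individuals), 2
                    ),
                    "no_match_pct": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    order = (
        df[df.method == metric]
        .sort_values(["correct_pct", "region"], ascending=[False, True])
        .region.tolist()
    )
    df["region"] = pd.Categorical(df.region, categories=order, ordered=True)
    return df.sort_values(["region", "method"]).reset_index(drop=True)
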