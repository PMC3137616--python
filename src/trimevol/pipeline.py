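"""Pipeline configuration and orchestration.

A YAML config toggles the five analysis stages (classify, entropy, recomb,
select, coloc), carries their input paths and options, and one master seed
from which per-stage seeds are derived.  Reports are plain-text key=value
summaries plus tab-separated per-stage tables, all deterministic for a
given config (no timestamps), so runs can be diffed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import read_alignment
from .classify import calls_to_frame, classify_table, detect_novel_combinations, call_like_variants
from .entropy import profile_alignment
from .enrichment import (
    read_chrom_sizes,
    read_gene_table,
    read_marker_table,
    run_colocalization,
    write_neighbourhood_bed,
    GenomeAnnotation,
)
from .recombination import scan_breakpoints, segment_selection_tests
from .selection import FitOptions, fit_site_model, lrt, site_posteriors

STAGE_ORDER = ("classify", "entropy", "recomb", "select", "coloc")

_STAGE_KEYS = {
    "classify": {"enabled", "domain_table", "identity_matrix", "like_threshold"},
    "entropy": {"enabled", "alignment", "max_gap_fraction"},
    "recomb": {
        "enabled",
        "alignment",
        "max_breakpoints",
        "grid_step",
        "min_segment",
        "segment_tests",
    },
    "select": {"enabled", "alignment", "tree", "models", "frequencies", "beb"},
    "coloc": {
        "enabled",
        "genes",
        "markers",
        "chrom_sizes",
        "family",
        "flank",
        "max_gap",
        "collapse",
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "trimevol_out"
    stages: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, opts in self.stages.items():
            if name not in _STAGE_KEYS:
                raise ConfigError(f"unknown stage {name!r}")
            unknown = set(opts) - _STAGE_KEYS[name]
            if unknown:
                raise ConfigError(f"unknown keys for stage {name!r}: {sorted(unknown)}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, {}).get("enabled", False))

    def stage_seed(self, stage: str) -> int:
        idx = STAGE_ORDER.index(stage)
        return int(
            np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _kv_lines(prefix: str, mapping: dict) -> list:
    lines = []
    for key in sorted(mapping):
        value = mapping[key]
        if isinstance(value, float):
            value = f"{value:.6g}"
        lines.append(f"{prefix}.{key}={value}")
    return lines


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and write a machine-readable summary.

    Returns {"summary": lines, "failures": {stage: message}, ...}.  A stage
    failure is recorded and later stages still run (stages are independent);
    callers should exit non-zero when failures is non-empty.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: list = [
        f"pipeline.version={__version__}",
        f"pipeline.seed={config.seed}",
    ]
    failures: dict = {}
    results: dict = {}

    def record(stage: str, mapping: dict) -> None:
        summary.extend(_kv_lines(stage, mapping))

    for stage in STAGE_ORDER:
        if not config.enabled(stage):
            continue
        opts = config.stages[stage]
        try:
            runner = _STAGE_RUNNERS[stage]
            results[stage] = runner(opts, out, config, record)
        except Exception as exc:
            failures[stage] = f"{type(exc).__name__}: {exc}"
            summary.append(f"{stage}.error={failures[stage]}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    results["summary"] = summary
    results["failures"] = failures
    return results


def _run_classify(opts, out, config, record):
    table = pd.read_csv(opts["domain_table"], sep="\t")
    calls = classify_table(table)
    frame = calls_to_frame(calls)
    if opts.get("identity_matrix"):
        idm = pd.read_csv(opts["identity_matrix"], sep="\t", index_col=0)
        call_like_variants(calls, idm, threshold=float(opts.get("like_threshold", 0.7)))
        frame = calls_to_frame(calls)
    novel = detect_novel_combinations(calls)
    frame.to_csv(out / "architecture_calls.tsv", sep="\t", index=False)
    novel.to_csv(out / "novel_architectures.tsv", sep="\t", index=False)
    counts = frame["trim_class"].value_counts().to_dict()
    record("classify", {"n_proteins": len(frame), "n_novel": len(novel),
                        **{f"class_{k}": v for k, v in counts.items()}})
    return frame


def _run_entropy(opts, out, config, record):
    aln = read_alignment(opts["alignment"], kind="protein")
    profile = profile_alignment(
        aln, max_gap_fraction=float(opts.get("max_gap_fraction", 0.5))
    )
    profile.to_frame().to_csv(out / "entropy_profile.tsv", sep="\t", index=False)
    record(
        "entropy",
        {
            "n_columns": profile.n_columns,
            "n_hypervariable": int(profile.hypervariable.sum()),
            "n_masked": int(profile.masked.sum()),
        },
    )
    return profile


def _run_recomb(opts, out, config, record):
    aln = read_alignment(opts["alignment"], kind="codon")
    aln, _ = aln.remove_gapped_columns() if any(
        "-" in s or "." in s for s in aln.seqs
    ) else (aln, None)
    partition = scan_breakpoints(
        aln,
        max_breakpoints=int(opts.get("max_breakpoints", 8)),
        grid_step=int(opts.get("grid_step", 3)),
        min_segment=int(opts.get("min_segment", 10)),
    )
    rows = [
        {
            "index": i + 1,
            "codon": b,
            "nucleotide": 3 * b,
        }
        for i, b in enumerate(partition.breakpoints)
    ]
    pd.DataFrame(rows, columns=["index", "codon", "nucleotide"]).to_csv(
        out / "breakpoints.tsv", sep="\t", index=False
    )
    record(
        "recomb",
        {
            "n_breakpoints": len(partition.breakpoints),
            "caic_single": partition.caic_single,
            "caic_total": partition.caic_total,
            "delta_caic": partition.delta_caic,
        },
    )
    if opts.get("segment_tests") and partition.breakpoints:
        seg = segment_selection_tests(
            aln, partition, options=FitOptions(seed=config.stage_seed("recomb"))
        )
        for i, s in enumerate(seg):
            if s.error:
                record("recomb", {f"segment{i+1}.error": s.error})
                continue
            for (null_id, alt_id), res in s.lrts.items():
                record(
                    "recomb",
                    {f"segment{i+1}.{null_id}_{alt_id}.p": res.p_value},
                )
    return partition


def _run_select(opts, out, config, record):
    from .trees import Tree

    aln = read_alignment(opts["alignment"], kind="codon")
    tree = Tree.from_newick(Path(opts["tree"]).read_text()) if opts.get("tree") else None
    models = list(opts.get("models", ["M1a", "M2a", "M7", "M8"]))
    freq = opts.get("frequencies", "F3x4")
    fit_options = FitOptions(seed=config.stage_seed("select"))
    fits: dict = {}
    prev = None
    for model_id in models:
        init = prev if prev and (prev.model_id, model_id) in (
            ("M0", "M1a"),
            ("M1a", "M2a"),
            ("M7", "M8"),
        ) else None
        fits[model_id] = fit_site_model(
            aln, tree, model_id, frequencies=freq, options=fit_options, init_from=init
        )
        prev = fits[model_id]
        f = fits[model_id]
        record(
            "select",
            {
                f"{model_id}.lnl": f.lnl,
                f"{model_id}.kappa": f.kappa,
                **(
                    {f"{model_id}.omega_pos": f.omega_pos, f"{model_id}.p_pos": f.p_pos}
                    if f.omega_pos is not None
                    else {}
                ),
            },
        )
    for null_id, alt_id in (("M1a", "M2a"), ("M7", "M8")):
        if null_id in fits and alt_id in fits:
            res = lrt(fits[null_id], fits[alt_id])
            record(
                "select",
                {
                    f"lrt.{null_id}_{alt_id}.two_delta_lnl": res.two_delta_lnl,
                    f"lrt.{null_id}_{alt_id}.p": res.p_value,
                },
            )
    for alt_id in ("M2a", "M8"):
        if alt_id in fits:
            method = "BEB" if (alt_id == "M2a" or opts.get("beb")) else "NEB"
            post = site_posteriors(fits[alt_id], aln, method=method)
            post.to_csv(out / f"site_posteriors_{alt_id}.tsv", sep="\t", index=False)
            record(
                "select",
                {f"{alt_id}.n_positive_sites": int(post["significant"].sum())},
            )
    return fits


def _run_coloc(opts, out, config, record):
    genes = read_gene_table(opts["genes"])
    markers = read_marker_table(opts["markers"])
    sizes = read_chrom_sizes(opts["chrom_sizes"])
    annotation = GenomeAnnotation(sizes, genes, markers)
    result, nb, occurrences = run_colocalization(
        annotation,
        opts["family"],
        flank=float(opts.get("flank", 5e6)),
        max_gap=float(opts.get("max_gap", 5e5)),
        collapse=bool(opts.get("collapse", True)),
    )
    write_neighbourhood_bed(nb, out / "neighbourhoods.bed")
    occurrences.to_csv(out / "occurrences.tsv", sep="\t", index=False)
    record(
        "coloc",
        {
            "chi2": result.chi2,
            "p_value": result.p_value,
            "family_inside": result.table[0, 0],
            "family_outside": result.table[0, 1],
            "n_genes_inside": nb.n_genes_inside,
            "neighbourhood_bp": nb.total_length,
        },
    )
    return result


_STAGE_RUNNERS = {
    "classify": _run_classify,
    "entropy": _run_entropy,
    "recomb": _run_recomb,
    "select": _run_select,
    "coloc": _run_coloc,
}
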