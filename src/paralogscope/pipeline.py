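"""End-to-end orchestration: sequences + pair table + expression -> report.

Every stage writes plain TSV/JSON into the output directory; reruns with
identical inputs and configuration are byte-identical.  A pre-computed pair
table (with ka/ks/omega columns filled) can drive the downstream stages
without any sequence input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from . import constraints, evolution, expression
from .io import (
    ExpressionTable,
    GenePairRecord,
    read_expression_table,
    read_fasta,
    read_pair_table,
    write_pair_table,
)

__all__ = ["RunConfig", "run_full_analysis", "compute_pair_kaks", "load_config"]

logger = logging.getLogger("paralogscope")


@dataclass(frozen=True)
class RunConfig:
    """Tunable constants of the full analysis."""

    ks_cutoff: float = 1.1
    omega_purifying: float = 0.3
    omega_positive: float = 3.0
    cosine_threshold: float = 0.5
    divergence_threshold: float = 50.0
    k_clusters: int = 16
    gamma_shape: float = 1.0
    method: str = "gMYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ks_cutoff, self.omega_purifying, self.omega_positive,
               self.divergence_threshold, self.gamma_shape) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.cosine_threshold < 1.0:
            raise ValueError("cosine_threshold must lie in (0, 1)")


def load_config(path: str | Path, base: Optional[RunConfig] = None) -> RunConfig:
    """Read ``key=value`` overrides (one per line, '#' comments) on defaults."""
    cfg = base or RunConfig()
    overrides = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in RunConfig.__dataclass_fields__:
            raise ValueError(f"unknown config key {key!r}")
        kind = RunConfig.__dataclass_fields__[key].type
        value = value.strip()
        if key == "method":
            overrides[key] = value
        elif key in ("k_clusters", "seed"):
            overrides[key] = int(value)
        else:
            overrides[key] = float(value)
    return replace(cfg, **overrides)


def compute_pair_kaks(
    fasta_path: str | Path,
    pairs: Sequence[GenePairRecord],
    method: str = "gMYN",
    gamma_shape: float = 1.0,
) -> list[GenePairRecord]:
    """Fill ka/ks/omega/divergence on pair records from coding sequences."""
    seqs = {s.gene_id: s for s in read_fasta(fasta_path)}
    updated = []
    for pair in pairs:
        for gid in (pair.gene1_id, pair.gene2_id):
            if gid not in seqs:
                raise KeyError(f"gene {gid!r} missing from FASTA input")
        est, divergence = evolution.pair_kaks_pipeline(
            seqs[pair.gene1_id], seqs[pair.gene2_id],
            method=method, gamma_shape=gamma_shape,
        )
        pair.ka = est.ka
        pair.ks = est.ks
        pair.omega = est.omega
        pair.saturated = est.saturated
        pair.divergence_pct = divergence
        if pair.length is None:
            pair.length = int(est.S + est.N) // 3
        updated.append(pair)
    return updated


def _dump_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _constraint_stage(pairs, cfg: RunConfig, outdir: Path) -> None:
    kept = constraints.filter_unsaturated(pairs, ks_max=cfg.ks_cutoff)
    logger.info("saturation filter kept %d of %d pairs", len(kept), len(pairs))
    with open(outdir / "classification.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tclass\tomega\tselection\trelation\n")
        for p in kept:
            fh.write(
                "\t".join(
                    [
                        p.gene1_id, p.gene2_id, p.paralog_class,
                        repr(p.omega) if p.omega is not None else "",
                        constraints.classify_selection(p.omega),
                        constraints.replicon_relation(p.replicon1, p.replicon2),
                    ]
                )
                + "\n"
            )
    with_omega = [p for p in kept if p.omega is not None]
    with open(outdir / "group_summary.tsv", "w", encoding="utf-8") as fh:
        fh.write("relation\tn\tmean_omega\tsd_omega\n")
        for g in constraints.summarize_omega_by_group(with_omega):
            fh.write(
                f"{g.group}\t{g.n}\t{repr(g.mean_omega)}\t"
                f"{repr(g.sd_omega) if g.sd_omega is not None else ''}\n"
            )
    bins = constraints.length_bin_frequencies(pairs)
    with open(outdir / "length_bins.tsv", "w", encoding="utf-8") as fh:
        fh.write("class\tbin\tfrequency\n")
        for cls in sorted(bins):
            for label, freq in bins[cls].items():
                fh.write(f"{cls}\t{label}\t{repr(freq)}\n")

    tests: dict[str, dict] = {}
    ins = [p for p in pairs if p.paralog_class == "in"]
    outs = [p for p in pairs if p.paralog_class == "out"]
    for field in ("ka", "ks"):
        x = [getattr(p, field) for p in ins if getattr(p, field) is not None]
        y = [getattr(p, field) for p in outs if getattr(p, field) is not None]
        if x and y:
            res = constraints.ks_two_sample(x, y)
            tests[f"ks_test_{field}_in_vs_out"] = {
                "D": res.statistic, "p": res.p_value,
            }
    for cls_name, subset in (("in", ins), ("out", outs)):
        for field in ("ka", "ks"):
            try:
                r, p = constraints.rate_divergence_correlation(subset, field)
            except ValueError:
                continue
            tests[f"correlation_{field}_vs_divergence_{cls_name}"] = {"R": r, "p": p}
    _dump_json(tests, outdir / "tests.json")


def _expression_stage(
    pairs, table: ExpressionTable, cfg: RunConfig, outdir: Path
) -> None:
    available = set(table.gene_ids)
    usable = []
    for p in pairs:
        if p.gene1_id in available and p.gene2_id in available:
            usable.append(p)
        else:
            logger.warning(
                "pair %s/%s dropped from expression analyses (gene missing)",
                p.gene1_id, p.gene2_id,
            )
    if not usable:
        logger.warning("no pairs with expression data; expression stages skipped")
        return
    averaged = expression.average_replicates(table)
    profiles = {
        prof.gene_id: prof
        for prof in expression.zscore_rows(averaged, table.gene_ids)
    }
    stats_rows = []
    for p in usable:
        u = profiles[p.gene1_id].values
        v = profiles[p.gene2_id].values
        cos = expression.cosine_similarity(u, v)
        r, tr = expression.pearson_and_transform(u, v)
        quadrant = (
            expression.classify_quadrant(cos, p.divergence_pct)
            if p.divergence_pct is not None
            else None
        )
        stats_rows.append((p, cos, r, tr, quadrant))
    with open(outdir / "expression_stats.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tclass\tcosine\tpearson_r\ttransformed_r\tquadrant\n")
        for p, cos, r, tr, quadrant in stats_rows:
            fh.write(
                "\t".join(
                    [
                        p.gene1_id, p.gene2_id, p.paralog_class, repr(cos), repr(r),
                        repr(tr) if tr is not None else "infinite",
                        quadrant or "",
                    ]
                )
                + "\n"
            )

    # clustering per paralog class + bidirectional matching
    by_class: dict[str, list] = {"in": [], "out": []}
    for p in usable:
        by_class[p.paralog_class].extend(
            [profiles[p.gene1_id], profiles[p.gene2_id]]
        )
    clusterings = {}
    for cls_name, profs in by_class.items():
        if not profs:
            continue
        k = min(cfg.k_clusters, len(profs))
        clusterings[cls_name] = expression.kmeans_hac(profs, k=k)
    with open(outdir / "clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("class\tgene\tcluster\n")
        for cls_name in sorted(clusterings):
            for gene, idx in clusterings[cls_name].assignments.items():
                fh.write(f"{cls_name}\t{gene}\t{idx}\n")
    report: dict[str, dict] = {}
    if "in" in clusterings and "out" in clusterings:
        for direction, (q, lib) in {
            "in_to_out": (clusterings["in"], clusterings["out"]),
            "out_to_in": (clusterings["out"], clusterings["in"]),
        }.items():
            matches, mean, sd = expression.match_clusters(q, lib)
            report[direction] = {
                "matches": [asdict(m) for m in matches],
                "mean_cosine": mean,
                "sd_cosine": sd,
            }
        for direction, (a, b) in {
            "genes_in_to_out": (by_class["in"], by_class["out"]),
            "genes_out_to_in": (by_class["out"], by_class["in"]),
        }.items():
            _, mean, sd = expression.gene_best_match(a, b)
            report[direction] = {"mean_cosine": mean, "sd_cosine": sd}
    _dump_json(report, outdir / "matches.json")

    # regressions of expression measures on constraints
    regressions: dict[str, dict] = {}
    complete = [
        (p, cos, tr)
        for p, cos, r, tr, _ in stats_rows
        if tr is not None and p.ka is not None and p.ks is not None
    ]
    for x_field in ("ka", "ks", "omega"):
        rows = [
            (getattr(p, x_field), cos, tr)
            for p, cos, tr in complete
            if getattr(p, x_field) is not None
        ]
        if len(rows) < 3:
            continue
        xs = [r[0] for r in rows]
        for y_name, ys in (
            ("transformed_r", [r[2] for r in rows]),
            ("expression_divergence", [1.0 - r[1] for r in rows]),
        ):
            try:
                slope, intercept, rr, pp = expression.regress_expression_vs_constraint(xs, ys)
            except ValueError:
                continue
            regressions[f"{y_name}_vs_{x_field}"] = {
                "slope": slope, "intercept": intercept, "R": rr, "p": pp,
            }
    _dump_json(regressions, outdir / "regressions.json")


def run_full_analysis(
    fasta_path: Optional[str | Path],
    pair_table_path: str | Path,
    expression_table_path: Optional[str | Path],
    outdir: str | Path,
    cfg: Optional[RunConfig] = None,
) -> Path:
    """Run all stages, writing report tables under ``outdir``.

    ``fasta_path`` may be omitted when the pair table already carries
    ka/ks/omega; missing expression input skips the expression stages with
    a warning.
    """
    cfg = cfg or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("configuration: %s", asdict(cfg))
        pairs = read_pair_table(pair_table_path)
        if fasta_path is not None:
            pairs = compute_pair_kaks(
                fasta_path, pairs, method=cfg.method, gamma_shape=cfg.gamma_shape
            )
        write_pair_table(pairs, outdir / "kaks.tsv")
        _constraint_stage(pairs, cfg, outdir)
        if expression_table_path is None:
            logger.warning("no expression table; expression stages skipped")
        else:
            _expression_stage(
                pairs, read_expression_table(expression_table_path), cfg, outdir
            )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
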