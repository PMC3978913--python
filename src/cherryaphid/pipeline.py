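"""End-to-end reproducible run: simulate -> sequence statistics ->
network/trees -> morphometrics -> report.

A single master seed drives every stage through deterministically derived
child seeds; rerunning with the same configuration produces byte-identical
artifacts (timings go to the log, never into data artifacts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import morpho, network, phylo, seqstats, synthetic

logger = logging.getLogger("cherryaphid")

CERASI_HAPS = synthetic.CERASI_HAPLOTYPES
BOREALIS_HAP = synthetic.BOREALIS_HAPLOTYPE


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "cherryaphid_run"
    # stage toggles
    run_sequences: bool = True
    run_network: bool = True
    run_trees: bool = True
    run_morphometrics: bool = True
    # thresholds
    correlation_threshold: float = 0.70
    correlation_alpha: float = 0.05
    connection_limit: int = 10
    bootstrap_reps: int = 100
    f_enter: float = 1.0
    f_remove: float = 0.0
    # synthetic-data knobs
    n_fixed_transitions: int = 23
    n_fixed_transversions: int = 15
    sample_effect_fraction: float = 0.25

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config fields: {unknown}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class RunReport:
    report: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    def to_markdown(self, path: str | Path) -> None:
        r = self.report
        lines = ["# Cherry aphid delimitation run", ""]
        if "haplotypes" in r:
            lines += ["## COI haplotypes", ""]
            lines += ["| haplotype | n sequences |", "|---|---|"]
            for hap, count in r["haplotypes"]["counts"].items():
                lines.append(f"| {hap} | {count} |")
            lines.append("")
            sc = r["site_classification"]
            lines.append(
                f"Alignment of {r['alignment_length']} bp: "
                f"{sc['variable-uninformative'] + sc['parsimony-informative']} "
                f"variable sites, {sc['parsimony-informative']} parsimony-"
                f"informative."
            )
            lines.append("")
        if "divergence" in r:
            lines += ["## K2P divergence (%)", ""]
            for name, s in r["divergence"].items():
                lines.append(
                    f"- {name}: {s['min_pct']} - {s['max_pct']} "
                    f"(mean {s['mean_pct']}, {s['n_pairs']} pairs)"
                )
            lines.append("")
        if "network" in r:
            lines += ["## Haplotype network", ""]
            for a, b, steps in r["network"]["edges"]:
                lines.append(f"- hap{a} -- hap{b}: {steps} step(s)")
            lines.append(
                f"\nRoot candidate: hap{r['network']['root_candidate']}"
            )
            lines.append("")
        if "trees" in r:
            lines += ["## Trees", ""]
            lines.append(f"NJ (K2P): `{r['trees']['nj_newick']}`")
            lines.append(
                f"\nExhaustive MP: length {r['trees']['mp_length']}, "
                f"CI = {r['trees']['mp_ci']:.2f}, RI = {r['trees']['mp_ri']:.2f} "
                f"({r['trees']['mp_n_best']} best of "
                f"{r['trees']['mp_n_topologies']} topologies)"
            )
            lines.append("")
        if "morphometrics" in r:
            m = r["morphometrics"]
            lines += ["## Morphometrics", ""]
            lines.append(
                f"- correlation filter: {len(m['removed_characters'])} removed "
                f"({', '.join(m['removed_characters'])}); "
                f"{m['n_retained']} retained"
            )
            lines.append(
                f"- stepwise inclusion order: {', '.join(m['inclusion_order'])}"
            )
            hv = m["holdout_validation"]["per_taxon"]
            for taxon, s in hv.items():
                lines.append(
                    f"- hold-out {taxon}: {s['n_correct']}/{s['n']} correct "
                    f"({s['percent']}%)"
                )
            rc = m["train_reclassification"]["per_taxon"]
            for taxon, s in rc.items():
                lines.append(
                    f"- training reclassification {taxon}: "
                    f"{s['n_correct']}/{s['n']} ({s['percent']}%)"
                )
            lines.append("")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))


def _hap_id_map(table: network.HaplotypeTable) -> dict[int, int]:
    """Map collapsed haplotype ids -> generator haplotype numbers using
    the record-id metadata (``sample|host|hapN``)."""
    out = {}
    for h in table.haplotypes:
        tags = {m.split("|")[-1] for m in h.members}
        if len(tags) == 1:
            tag = tags.pop()
            if tag.startswith("hap") and tag[3:].isdigit():
                out[h.hap_id] = int(tag[3:])
    return out


def run_all(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    report: dict = {"seed": config.seed}
    t0 = time.perf_counter()

    scheme = synthetic.HaplotypeScheme()
    alignment = synthetic.build_alignment(scheme, seed=config.seed)
    og_spec = synthetic.OutgroupSpec(
        n_fixed_transitions=config.n_fixed_transitions,
        n_fixed_transversions=config.n_fixed_transversions,
    )
    full = synthetic.add_outgroup(alignment, og_spec, seed=config.seed,
                                  scheme=scheme)
    seqstats.write_fasta(alignment, out / "coi_ingroup.fasta")
    seqstats.write_fasta(full, out / "coi_with_outgroup.fasta")
    logger.info("simulate: %d + outgroup sequences (%.2fs)",
                len(alignment), time.perf_counter() - t0)

    ingroup_ids = alignment.ids
    cerasi_ids = [i for i in ingroup_ids if not i.endswith("hap5")]
    borealis_ids = [i for i in ingroup_ids if i.endswith("hap5")]

    if config.run_sequences:
        t = time.perf_counter()
        sites = seqstats.classify_sites(alignment)
        report["alignment_length"] = alignment.length
        report["site_classification"] = seqstats.site_class_counts(sites)
        report["base_composition"] = {
            k: round(v, 4)
            for k, v in seqstats.base_composition(alignment).as_dict().items()
        }
        report["stop_codon_frame"] = seqstats.zero_stop_frame(full)
        dm = seqstats.distance_matrix(full)
        dm.to_tsv(out / "k2p_distances.tsv")
        report["divergence"] = {
            "cerasi_intraspecific": dm.summary(cerasi_ids),
            "cerasi_vs_borealis": dm.summary(cerasi_ids, borealis_ids),
            "cerasi_vs_outgroup": dm.summary(
                cerasi_ids, [synthetic.OUTGROUP_ID]
            ),
            "borealis_vs_outgroup": dm.summary(
                borealis_ids, [synthetic.OUTGROUP_ID]
            ),
        }
        logger.info("seqstats done (%.2fs)", time.perf_counter() - t)

    table = network.collapse_haplotypes(alignment)
    id_map = _hap_id_map(table)
    report["haplotypes"] = {
        "counts": {
            f"hap{id_map.get(h.hap_id, h.hap_id)}": h.count
            for h in table.haplotypes
        }
    }

    if config.run_network:
        t = time.perf_counter()
        net = network.build_network(table, config.connection_limit)
        net = network.root_weights(net, table)
        net.to_tsv(out / "network_edges.tsv", out / "network_nodes.tsv")
        (out / "network.dot").write_text(net.to_dot())
        report["network"] = {
            "edges": [
                [id_map.get(a, a), id_map.get(b, b), s] for a, b, s in net.edges
            ],
            "root_candidate": id_map.get(net.root_candidate, net.root_candidate),
            "root_weights": {
                f"hap{id_map.get(nid, nid)}": round(
                    net.graph.nodes[nid]["root_weight"], 4
                )
                for nid in sorted(net.graph.nodes)
            },
        }
        logger.info("network done (%.2fs)", time.perf_counter() - t)

    if config.run_trees:
        t = time.perf_counter()
        hap_full = network.collapse_haplotypes(full)
        hap_align = seqstats.Alignment(
            [(h.members[0], h.sequence) for h in hap_full.haplotypes]
        )
        nj = phylo.nj_k2p(hap_align)
        (out / "nj_haplotypes.nwk").write_text(nj.newick() + "\n")
        mp = phylo.exhaustive_mp(hap_align)
        cerasi_only = alignment.subset(cerasi_ids)
        mp_cerasi = phylo.exhaustive_mp(cerasi_only)
        support = phylo.bootstrap_support(
            hap_align, phylo.nj_k2p, n_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        phylo.support_table_tsv(support, out / "bootstrap_support.tsv")
        report["trees"] = {
            "nj_newick": nj.newick(),
            "mp_length": mp.length,
            "mp_ci": mp.ci,
            "mp_ri": mp.ri,
            "mp_n_best": len(mp.best_trees),
            "mp_n_topologies": mp.n_topologies,
            "mp_cerasi_ci": mp_cerasi.ci,
            "mp_cerasi_ri": mp_cerasi.ri,
            "bootstrap_reps": config.bootstrap_reps,
        }
        logger.info("trees done (%.2fs)", time.perf_counter() - t)

    if config.run_morphometrics:
        t = time.perf_counter()
        design = synthetic.CohortDesign()
        spec = synthetic.MorphoGenSpec(
            sample_effect_fraction=config.sample_effect_fraction
        )
        morph = synthetic.generate_morphometrics(design, spec, seed=config.seed)
        morpho.write_morph_tsv(morph, out / "morphometrics.tsv")
        train = morph[morph["role"] == "train"]
        corr = morpho.correlation_filter(
            train, config.correlation_threshold, config.correlation_alpha
        )
        corr.to_frame().to_csv(out / "correlation_report.tsv", sep="\t",
                               index=False)
        trace = morpho.stepwise_wilks(
            train, corr.retained, "sample_id",
            f_enter=config.f_enter, f_remove=config.f_remove,
        )
        trace.final_table().to_csv(out / "stepwise_trace.tsv", sep="\t",
                                   index=False)
        cv = morpho.canonical_variates(train, corr.retained, "sample_id")
        cv.group_scores.to_csv(out / "canonical_group_scores.tsv", sep="\t")
        fitted = morpho.fit_two_group_ldf(morph)
        train_assign = morpho.apply_key(train, morpho.PRINTED_KEY)
        reclass = morpho.classification_summary(train_assign, train["taxon"])
        morpho.sample_mean_ldf_table(morph).to_csv(
            out / "sample_mean_ldf.tsv", sep="\t", index=False
        )
        report["morphometrics"] = {
            "removed_characters": corr.removed,
            "n_retained": len(corr.retained),
            "inclusion_order": trace.inclusion_order,
            "final_wilks_lambda": round(trace.final_lambda, 4),
            "cv1_separates_hosts": bool(
                _cv1_separates_hosts(cv.group_scores, train)
            ),
            "fitted_key": {
                "coefficients": {k: round(v, 6)
                                 for k, v in fitted.coefficients.items()},
                "intercept": round(fitted.intercept, 6),
            },
            "holdout_validation": morpho.holdout_validation(
                morph, morpho.PRINTED_KEY
            ).as_dict(),
            "train_reclassification": reclass.as_dict(),
        }
        logger.info("morphometrics done (%.2fs)", time.perf_counter() - t)

    run_report = RunReport(report)
    run_report.to_json(out / "report.json")
    run_report.to_markdown(out / "report.md")
    logger.info("run complete (%.2fs total)", time.perf_counter() - t0)
    return run_report


def _cv1_separates_hosts(group_scores, train) -> bool:
    host_by_sample = train.groupby("sample_id")["taxon"].first()
    cv1 = group_scores["CV1"]
    cerasi = cv1[host_by_sample.loc[cv1.index] == "cerasi"]
    pruni = cv1[host_by_sample.loc[cv1.index] == "pruniavium"]
    return bool(
        (cerasi.min() > 0 and pruni.max() < 0)
        or (pruni.min() > 0 and cerasi.max() < 0)
    )
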