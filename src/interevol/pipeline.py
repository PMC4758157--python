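"""End-to-end orchestration: simulate -> detect -> analyse -> report.

`run_pipeline` executes every stage of the analysis on a synthetic
scenario and writes per-stage artifacts plus a machine-readable summary:

1. generate complexes with planted interfaces and paralogue models;
2. detect interfaces geometrically (the planted truth is written alongside
   but never consulted by the analysis);
3. simulate post-duplication interaction loss and build the
   evidence-filtered network;
4. per-pair divergence accounting: region substitution counts, relative
   interface rate with the >2x exclusion filter, the interface x
   interaction 2x2 table, the interface substitution matrix, and the
   correlation of relative rate with SIR;
5. per-site selection classification on per-pair codon alignments whose
   column omega classes follow the pair's interface layout, with
   Kruskal-Wallis / Mann-Whitney / Benjamini-Hochberg group comparisons;
6. the contact-preservation predictor evaluated against observed
   interaction status;
7. loss-rate estimation by both routes (planted ancestral truth, and
   network inference whose double-loss bias is reported, not corrected).

Every output directory carries the config and its hash; identical configs
produce identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import divergence as dv
from . import geometry as geo
from . import network as net
from . import selection as sel
from .contacts import (
    evaluate_predictions,
    predict_interaction_conservation,
    substitution_contact_outcome,
)
from .simulate import (
    ScenarioConfig,
    gen_codon_alignment,
    gen_duplicate_pair,
    gen_toy_complex,
    simulate_interaction_loss,
    write_truth_json,
)
from .structures import write_pdb

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    margin: float = geo.DEFAULT_CONTACT_MARGIN
    network_mode: str = "MC"
    alpha: float = sel.ALPHA
    hub_threshold: int = net.HUB_DEGREE_THRESHOLD
    rate_filter_cap: float = dv.RATE_FILTER_CAP
    n_sasa_sample: int = 3
    n_pdb_sample: int = 3
    run_selection: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["site_classes"] = [
            list(c) for c in d["scenario"]["site_classes"]
        ]
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_pipeline(config: RunConfig, output_dir: str | Path) -> dict[str, Any]:
    """Run every stage on a synthetic scenario; return (and write) the summary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen = config.scenario
    log: list[str] = []

    # -- stage 1-2: structures, detected interfaces, paralogue models ------
    pairs: list[dv.DuplicatePair] = []
    templates = {}
    models = {}
    truths = {}
    detected_ifaces = {}
    diverged_flags: dict[str, bool] = {}
    predictions: dict[str, str] = {}
    for k in range(scen.n_pairs):
        pid = f"pair{k:04d}"
        template, planted = gen_toy_complex(
            scen, pair_index=k, margin=config.margin, name=pid
        )
        contacts = geo.detect_atom_contacts(
            template, "A", "B", margin=config.margin
        )
        iface = geo.identify_interface(contacts, chain_pair=("A", "B"))
        pair, model, truth = gen_duplicate_pair(
            template, iface, scen, pair_id=pid, pair_index=k
        )
        pairs.append(pair)
        templates[pid], models[pid], truths[pid] = template, model, truth
        detected_ifaces[pid] = iface

        # contact outcomes for substituted/deleted interface residues
        outcomes = []
        model_index = {}
        rank = 0
        for t in truth:
            if not t.deleted:
                rank += 1
                model_index[t.site] = rank
        for t in truth:
            if not t.interface or not (t.substituted or t.deleted):
                continue
            outcomes.append(
                substitution_contact_outcome(
                    template,
                    model,
                    iface,
                    pid,
                    t.site,
                    model_residue_index=model_index.get(t.site),
                    margin=config.margin,
                )
            )
        predictions[pid] = predict_interaction_conservation(outcomes)
        diverged_flags[pid] = any(not o.preserved for o in outcomes)

    for k in range(min(config.n_pdb_sample, scen.n_pairs)):
        pid = f"pair{k:04d}"
        write_pdb(templates[pid], out / f"{pid}_template.pdb")
        write_pdb(models[pid], out / f"{pid}_model.pdb")
        geo.interface_to_tsv(detected_ifaces[pid], out / f"{pid}_interface.tsv")
    log.append(f"generated {scen.n_pairs} complexes and paralogue models")

    # -- stage 3: interaction network --------------------------------------
    records, loss_truth = simulate_interaction_loss(
        scen, diverged_pair_flags=diverged_flags
    )
    net.write_evidence_tsv(records, out / "evidence.tsv")
    write_truth_json(loss_truth, out / "loss_truth.json")
    network = net.build_network(records, mode=config.network_mode)
    network.to_edge_tsv(out / "network_edges.tsv")
    (out / "network_summary.json").write_text(
        json.dumps(network.summary(), indent=2) + "\n"
    )

    # -- stage 4: divergence accounting -------------------------------------
    excluded: dict[str, str] = {}
    calls: list[dv.DivergenceCall] = []
    call_pairs: list[dv.DuplicatePair] = []
    call_columns = []
    ratios: dict[str, float] = {}
    sirs: dict[str, float] = {}
    pair_rows = []
    for pair in pairs:
        cols = dv.map_interface_to_alignment(pair)
        iface_counts, non_counts = dv.count_substitutions(pair, cols)
        try:
            rel = dv.relative_interface_rate(
                iface_counts, non_counts, cap=config.rate_filter_cap
            )
        except net.PairExcluded as exc:
            excluded[pair.pair_id] = f"rate: {exc}"
            rel = None
        try:
            call = dv.classify_pair_divergence(pair, network, cols)
            sir = net.compute_sir(
                pair.pair_id, pair.gene_a, pair.gene_b, network
            ).sir
        except net.PairExcluded as exc:
            excluded[pair.pair_id] = f"network: {exc}"
            call, sir = None, None
        if call is not None:
            calls.append(call)
            call_pairs.append(pair)
            call_columns.append(cols)
            sirs[pair.pair_id] = sir
        if (
            rel is not None
            and rel.defined
            and not rel.excluded
            and call is not None
        ):
            ratios[pair.pair_id] = rel.ratio
        pair_rows.append(
            "\t".join(
                str(v)
                for v in (
                    pair.pair_id,
                    iface_counts.n_sites,
                    iface_counts.n_subs,
                    iface_counts.n_gaps,
                    non_counts.n_sites,
                    non_counts.n_subs,
                    non_counts.n_gaps,
                    f"{rel.ratio:.4f}" if rel and rel.defined else "NA",
                    int(rel.excluded) if rel else "NA",
                    call.interface_status if call else "NA",
                    call.interaction_status if call else "NA",
                    f"{sir:.4f}" if sir is not None else "NA",
                )
            )
        )
    header = (
        "pair\tiface_sites\tiface_subs\tiface_gaps\tnon_sites\tnon_subs"
        "\tnon_gaps\trelative_rate\trate_excluded\tinterface_status"
        "\tinteraction_status\tsir"
    )
    (out / "pairs.tsv").write_text(header + "\n" + "\n".join(pair_rows) + "\n")

    table1 = dv.contingency_table(calls)
    matrix = dv.build_substitution_matrix(call_pairs, calls, call_columns)
    (out / "substitution_matrix.tsv").write_text(matrix.to_long_tsv())

    shared = sorted(set(ratios) & set(sirs))
    correlation = None
    if len(shared) >= 3:
        try:
            correlation = net.correlate_divergence_with_sir(
                [ratios[p] for p in shared], [sirs[p] for p in shared]
            )
        except ValueError as exc:
            log.append(f"correlation skipped: {exc}")

    # -- loss rate: truth route and network-inference route ------------------
    truth_est = None
    if loss_truth["total_ancestral_interactions"] > 0:
        truth_est = net.estimate_loss_rate(
            loss_truth["total_losses"],
            loss_truth["total_ancestral_interactions"],
            scen.divergence_time,
        )
    l_net = a_net = 0
    for pair in pairs:
        try:
            a, l = net.infer_ancestral_interactions(
                pair.pair_id, pair.gene_a, pair.gene_b, network
            )
        except net.PairExcluded:
            continue
        a_net += a
        l_net += l
    network_est = (
        net.estimate_loss_rate(l_net, a_net, scen.divergence_time)
        if a_net
        else None
    )

    # -- stage 5: selection ---------------------------------------------------
    selection_summary = None
    if config.run_selection:
        groups_negative: dict[str, list[float]] = {
            "interface_conserved": [],
            "interface_diverged": [],
            "non_interface_conserved": [],
            "non_interface_diverged": [],
        }
        groups_neutral = {k: [] for k in groups_negative}
        call_by_pair = {c.pair_id: c for c in calls}
        for k, pair in enumerate(pairs):
            call = call_by_pair.get(pair.pair_id)
            if call is None:
                continue
            cols = dv.map_interface_to_alignment(pair)
            per_site = [
                ("interface", scen.omega_interface)
                if flag
                else ("non_interface", scen.omega_noninterface)
                for flag in cols
            ]
            alignment, _ = gen_codon_alignment(
                scen, per_site_omegas=per_site, stream=k
            )
            sites = sel.classify_alignment_sites(
                scen.tree, alignment, alpha=config.alpha
            )
            props = sel.region_selection_proportions(sites, cols)
            status = call.interaction_status
            for region in ("interface", "non_interface"):
                if props[region] is None:
                    continue
                groups_negative[f"{region}_{status}"].append(
                    props[region]["negative"]
                )
                groups_neutral[f"{region}_{status}"].append(
                    props[region]["neutral"]
                )
        selection_summary = {
            "groups_negative_median": {
                g: _round(float(np.median(v))) if v else None
                for g, v in groups_negative.items()
            },
            "groups_neutral_median": {
                g: _round(float(np.median(v))) if v else None
                for g, v in groups_neutral.items()
            },
        }
        usable = {g: v for g, v in groups_negative.items() if len(v) >= 2}
        if len(usable) >= 2:
            selection_summary["comparisons_negative"] = (
                sel.compare_selection_groups(usable, alpha=config.alpha)
            )
        (out / "selection_groups.json").write_text(
            json.dumps(selection_summary, indent=2, sort_keys=True) + "\n"
        )

    # -- stage 6: contact-preservation predictor ------------------------------
    observed = {
        c.pair_id: c.interaction_status for c in calls
    }
    eval_ids = sorted(set(predictions) & set(observed))
    evaluation = evaluate_predictions(
        [predictions[p] for p in eval_ids], [observed[p] for p in eval_ids]
    )
    evaluation.to_json(out / "evaluation.json")
    (out / "predictions.tsv").write_text(
        "pair\tpredicted\tobserved\n"
        + "\n".join(
            f"{p}\t{predictions[p]}\t{observed[p]}" for p in eval_ids
        )
        + "\n"
    )

    # -- burial / atom-role reporting on a structure sample -------------------
    burial = None
    if config.n_sasa_sample > 0:
        buried = exposed = 0
        role_fracs = []
        for k in range(min(config.n_sasa_sample, scen.n_pairs)):
            pid = f"pair{k:04d}"
            template = templates[pid]
            iface = detected_ifaces[pid]
            sasa = geo.shrake_rupley_sasa(template, "A")
            for r in sorted(iface.residues_a):
                rtype = template.residue_type("A", r)
                cls = geo.classify_buried(
                    sasa[r], geo.MAX_SASA[rtype]
                )
                buried += cls == "buried"
                exposed += cls == "exposed"
            role_fracs.append(
                geo.side_chain_specific_fraction(iface.contacts)
            )
        total = buried + exposed
        burial = {
            "interface_residues_sampled": total,
            "buried_fraction": _round(buried / total) if total else None,
            "side_chain_specific_contact_fraction": _round(
                float(np.mean(role_fracs))
            ),
        }

    summary: dict[str, Any] = {
        "config_hash": config.config_hash,
        "n_pairs": scen.n_pairs,
        "n_excluded": len(excluded),
        "exclusions": excluded,
        "network": network.summary(),
        "hubs": net.find_hubs(network, threshold=config.hub_threshold),
        "loss_rate_truth_route": _round(truth_est.rate, 8) if truth_est else None,
        "loss_rate_network_route": (
            _round(network_est.rate, 8) if network_est else None
        ),
        "table1": table1,
        "median_relative_interface_rate": (
            _round(float(np.median(list(ratios.values())))) if ratios else None
        ),
        "n_rate_pairs": len(ratios),
        "sir_correlation": (
            {k: _round(v) for k, v in correlation.items()}
            if correlation
            else None
        ),
        "substitution_matrix_total": matrix.total(),
        "selection": selection_summary,
        "predictor": {
            "tp": evaluation.tp,
            "fp": evaluation.fp,
            "fn": evaluation.fn,
            "tn": evaluation.tn,
            "precision": _round(evaluation.precision),
            "recall": _round(evaluation.recall),
            "f_score": _round(evaluation.f_score),
        },
        "burial": burial,
        "log": log,
    }
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
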