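"""Assay cross-prediction networks and the merged general model.

Each assay in a panel trains its own classifier; every ordered pair
(train assay, test assay) gets a directed ROC score. Two assays are
connected in the (undirected) prediction network only when prediction is
bidirectional: both directed ROC scores reach the threshold (default
0.60, inclusive). Connected components identify groups of assays probing
overlapping chemistry/mechanisms; a component's datasets can be merged
into one training set for a general cytotoxicity model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import networkx as nx
import numpy as np

from . import bayes, evaluate
from .data_model import AssayDataset, LabelledSet, MoleculeRecord
from .label import filter_min_actives

DEFAULT_ROC_THRESHOLD = 0.60

PanelEntry = tuple[AssayDataset, LabelledSet]


@dataclass
class CrossROCResult:
    roc_matrix: dict[tuple[str, str], float | None]
    nodes: dict[str, dict[str, Any]]   # assay_id -> {n_compounds, n_toxic}
    excluded: dict[str, str]           # assay_id -> reason


def cross_roc_matrix(
    panel: Sequence[PanelEntry],
    store: Mapping[str, MoleculeRecord],
    min_actives: int = 10,
    exclude_overlap: bool = False,
    **fit_kwargs: Any,
) -> CrossROCResult:
    """Directed ROC matrix over a panel of labelled assays.

    Panels must be homogeneous in readout (percent-inhibition and IC50
    networks are built separately). Assays with fewer than ``min_actives``
    toxic compounds, or on which a model cannot be fit, are excluded and
    reported. The matrix is generally asymmetric. Compounds shared
    between train and test assays stay in the test set unless
    ``exclude_overlap`` is set.
    """
    readouts = {ds.readout for ds, _ in panel}
    if len(readouts) > 1:
        raise ValueError(
            f"panel mixes readouts {sorted(readouts)}; build one network per readout"
        )
    excluded: dict[str, str] = {}
    usable: list[PanelEntry] = []
    models: dict[str, bayes.BayesModel] = {}
    for ds, labels in panel:
        if not filter_min_actives(labels, min_actives):
            excluded[ds.assay_id] = (
                f"{labels.n_toxic} toxic compounds < min_actives={min_actives}"
            )
            continue
        recs = [store[cid] for cid in ds.measurements]
        try:
            models[ds.assay_id] = bayes.fit(recs, labels, **fit_kwargs)
        except bayes.DegenerateTrainingError as exc:
            excluded[ds.assay_id] = f"model could not be trained: {exc}"
            continue
        usable.append((ds, labels))

    nodes = {
        ds.assay_id: {"n_compounds": len(ds), "n_toxic": labels.n_toxic}
        for ds, labels in usable
    }
    matrix: dict[tuple[str, str], float | None] = {}
    for ds_i, _ in usable:
        model = models[ds_i.assay_id]
        train_ids = set(ds_i.measurements)
        for ds_j, labels_j in usable:
            if ds_j.assay_id == ds_i.assay_id:
                continue
            test_ids = [
                cid for cid in ds_j.measurements
                if not (exclude_overlap and cid in train_ids)
            ]
            scores = {cid: bayes.score(model, store[cid]).score for cid in test_ids}
            try:
                auc = evaluate.roc_auc(
                    scores, LabelledSet({c: labels_j.labels[c] for c in test_ids})
                ).auc
            except evaluate.SingleClassError:
                auc = None
            matrix[(ds_i.assay_id, ds_j.assay_id)] = auc
    return CrossROCResult(roc_matrix=matrix, nodes=nodes, excluded=excluded)


@dataclass
class PredictionNetwork:
    nodes: dict[str, dict[str, Any]]
    roc_matrix: dict[tuple[str, str], float | None]
    threshold: float
    inclusive: bool
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)))

    def largest_component(self) -> set[str]:
        comps = self.components
        if not comps:
            raise ValueError("network has no nodes")
        return comps[0]


def build_network(
    cross: CrossROCResult,
    threshold: float = DEFAULT_ROC_THRESHOLD,
    inclusive: bool = True,
) -> PredictionNetwork:
    """Threshold the directed ROC matrix into the bidirectional network.

    An edge {i, j} exists iff BOTH directed scores meet the threshold
    (>= when ``inclusive``, the default; > otherwise). No self-edges.
    """
    ok = (lambda a: a is not None and a >= threshold) if inclusive else (
        lambda a: a is not None and a > threshold)
    g = nx.Graph()
    for aid, attrs in cross.nodes.items():
        g.add_node(aid, **attrs)
    for (i, j), a_ij in cross.roc_matrix.items():
        if i < j:
            a_ji = cross.roc_matrix.get((j, i))
            if ok(a_ij) and ok(a_ji):
                g.add_edge(i, j, roc_forward=a_ij, roc_reverse=a_ji)
    return PredictionNetwork(
        nodes=cross.nodes, roc_matrix=cross.roc_matrix,
        threshold=threshold, inclusive=inclusive, graph=g,
    )


def merge_component(
    network: PredictionNetwork,
    component: set[str],
    panel: Sequence[PanelEntry],
    store: Mapping[str, MoleculeRecord],
    policy: str = "any_toxic",
) -> tuple[list[MoleculeRecord], LabelledSet]:
    """Merge the member assays of one component into a single training set.

    ``any_toxic``: a compound seen in several assays is toxic if toxic in
    any of them (alert semantics for a safety triage tool), one record
    per compound. ``majority``: toxic if toxic in more than half of its
    appearances. ``keep_duplicates``: one record per measurement, ids
    suffixed with the assay id.
    """
    if not component:
        raise ValueError("component is empty")
    if policy not in {"any_toxic", "majority", "keep_duplicates"}:
        raise ValueError(f"unknown merge policy {policy!r}")
    member = [(ds, lab) for ds, lab in panel if ds.assay_id in component]
    if not member:
        raise ValueError("no panel assays in the requested component")

    if policy == "keep_duplicates":
        records, labels = [], {}
        for ds, lab in member:
            for cid in ds.measurements:
                dup_id = f"{cid}@{ds.assay_id}"
                r = store[cid]
                records.append(MoleculeRecord(
                    id=dup_id, smiles=r.smiles, features=r.features,
                    descriptors=dict(r.descriptors)))
                labels[dup_id] = lab.labels[cid]
        return records, LabelledSet(labels, {"kind": "merged", "policy": policy,
                                             "assays": sorted(component)})

    votes: dict[str, list[bool]] = {}
    for ds, lab in member:
        for cid in ds.measurements:
            votes.setdefault(cid, []).append(lab.labels[cid])
    if policy == "any_toxic":
        labels = {cid: any(v) for cid, v in votes.items()}
    else:
        labels = {cid: sum(v) * 2 > len(v) for cid, v in votes.items()}
    records = [store[cid] for cid in labels]
    return records, LabelledSet(labels, {"kind": "merged", "policy": policy,
                                         "assays": sorted(component)})


@dataclass
class MergedModelResult:
    cv_pi: evaluate.CVResult
    cv_ic50: evaluate.CVResult
    cv_combined: evaluate.CVResult
    agreement: evaluate.AgreementTable
    network_pi: PredictionNetwork
    network_ic50: PredictionNetwork
    combined_model: bayes.BayesModel
    holdout_ids: set[str]


def merged_model_pipeline(
    panel_pi: Sequence[PanelEntry],
    panel_ic50: Sequence[PanelEntry],
    store: Mapping[str, MoleculeRecord],
    holdout_fraction: float = 0.10,
    threshold: float = DEFAULT_ROC_THRESHOLD,
    k: int = 5,
    seed: int = 0,
    merge_policy: str = "any_toxic",
    min_actives: int = 10,
    **fit_kwargs: Any,
) -> MergedModelResult:
    """The one-general-model procedure.

    Builds the percent-inhibition and IC50 prediction networks, merges
    the largest component of each into a training set, cross-validates
    the two sub-models and the combined (union) model, and — on a
    held-out fraction drawn from both training sets — bins the two
    sub-models' scores against each other to check they agree before
    merging.
    """
    if merge_policy == "keep_duplicates":
        raise ValueError(
            "merged_model_pipeline needs one record per compound; "
            "use any_toxic or majority"
        )
    rng = np.random.default_rng(seed)

    def merged(panel: Sequence[PanelEntry]) -> tuple[list[MoleculeRecord], LabelledSet, PredictionNetwork]:
        cross = cross_roc_matrix(panel, store, min_actives=min_actives,
                                 **fit_kwargs)
        net = build_network(cross, threshold=threshold)
        recs, labs = merge_component(net, net.largest_component(), panel, store,
                                     policy=merge_policy)
        return recs, labs, net

    recs_pi, labs_pi, net_pi = merged(panel_pi)
    recs_ic, labs_ic, net_ic = merged(panel_ic50)

    # combined training set: union with the same conflict policy
    union_votes: dict[str, list[bool]] = {}
    for labs in (labs_pi, labs_ic):
        for cid, v in labs.labels.items():
            union_votes.setdefault(cid, []).append(v)
    if merge_policy == "majority":
        union_labels = {cid: sum(v) * 2 > len(v) for cid, v in union_votes.items()}
    else:
        union_labels = {cid: any(v) for cid, v in union_votes.items()}
    labs_union = LabelledSet(union_labels, {"kind": "merged", "policy": merge_policy,
                                            "source": "pi+ic50"})
    recs_union = [store[cid] for cid in union_labels]

    cv_pi = evaluate.kfold_cv(recs_pi, labs_pi, k=k, seed=seed, **fit_kwargs)
    cv_ic = evaluate.kfold_cv(recs_ic, labs_ic, k=k, seed=seed, **fit_kwargs)
    cv_union = evaluate.kfold_cv(recs_union, labs_union, k=k, seed=seed, **fit_kwargs)

    # held-out agreement check between the two sub-models
    def holdout(ids: list[str]) -> set[str]:
        n = max(1, int(round(holdout_fraction * len(ids))))
        return set(np.array(sorted(ids), dtype=object)[rng.permutation(len(ids))][:n])

    held = holdout(list(labs_pi.labels)) | holdout(list(labs_ic.labels))
    def sub_model(recs, labs):
        train = [r for r in recs if r.id not in held]
        tl = LabelledSet({r.id: labs.labels[r.id] for r in train})
        return bayes.fit(train, tl, **fit_kwargs)

    m_pi = sub_model(recs_pi, labs_pi)
    m_ic = sub_model(recs_ic, labs_ic)
    held_recs = [store[cid] for cid in held]
    s_pi = {r.id: bayes.score(m_pi, r).score for r in held_recs}
    s_ic = {r.id: bayes.score(m_ic, r).score for r in held_recs}
    held_labels = LabelledSet({cid: labs_union.labels[cid] for cid in held})
    agreement = evaluate.score_agreement_table(s_pi, s_ic, held_labels)

    combined = bayes.fit(recs_union, labs_union, **fit_kwargs)
    return MergedModelResult(
        cv_pi=cv_pi, cv_ic50=cv_ic, cv_combined=cv_union,
        agreement=agreement, network_pi=net_pi, network_ic50=net_ic,
        combined_model=combined, holdout_ids=held,
    )


def export_network(net: PredictionNetwork, out_dir: str | Path,
                   basename: str = "network") -> dict[str, Path]:
    """Write the network as: 3-column directed-pairs TSV
    (``training_set<TAB>test_set<TAB>roc``), SIF, GraphML with node and
    edge attributes, and a JSON summary with components."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tsv = out_dir / f"{basename}_pairs.tsv"
    with tsv.open("w") as fh:
        fh.write("training_set\ttest_set\troc\n")
        for (i, j), a in sorted(net.roc_matrix.items()):
            fh.write(f"{i}\t{j}\t{'' if a is None else repr(a)}\n")
    paths["pairs_tsv"] = tsv

    sif = out_dir / f"{basename}.sif"
    with sif.open("w") as fh:
        connected = set()
        for i, j in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{i}\tpredicts\t{j}\n")
            connected |= {i, j}
        for n in sorted(set(net.graph.nodes) - connected):
            fh.write(f"{n}\n")
    paths["sif"] = sif

    graphml = out_dir / f"{basename}.graphml"
    nx.write_graphml(net.graph, graphml)
    paths["graphml"] = graphml

    summary = out_dir / f"{basename}_summary.json"
    summary.write_text(json.dumps({
        "threshold": net.threshold,
        "inclusive": net.inclusive,
        "nodes": net.nodes,
        "n_edges": net.graph.number_of_edges(),
        "components": [sorted(c) for c in net.components],
    }, indent=1))
    paths["summary_json"] = summary
    return paths
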