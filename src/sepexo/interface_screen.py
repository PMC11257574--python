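"""All-vs-all interface screening of pairwise predicted complex models.

The screen follows the standard heavy-atom contact convention: two residues
of different chains are in contact when their minimum non-hydrogen
inter-atomic distance is at or below a cutoff (default 4.0 A, inclusive).
Contacts are then filtered by per-residue confidence (pLDDT >= 50 on both
partners by default), models of a pair are ranked by mean pLDDT, and a
subunit pair counts as an interaction only when the rank-1 model of *each*
input order shows at least ``min_contacts`` filtered contacts -- the
bidirectional-order consensus criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import StructureModel

__all__ = [
    "ContactRecord",
    "InterfaceSet",
    "ScreenResult",
    "extract_contacts",
    "filter_by_plddt",
    "rank_models",
    "build_interface_set",
    "evaluate_pair",
    "screen_all_pairs",
    "screen_report",
]


@dataclass(frozen=True)
class ContactRecord:
    """An inter-chain residue pair within the distance cutoff."""

    chain_a_id: str
    res_a_index: int
    res_a_name: str
    chain_b_id: str
    res_b_index: int
    res_b_name: str
    min_distance: float  # A, minimum over non-hydrogen atom pairs


@dataclass
class InterfaceSet:
    """Contacts of one ordered input (e.g. Spn1:Sec3) at one model rank."""

    pair_label: tuple[str, str]  # unordered, stored sorted
    order_tag: str  # "A:B" in input order
    model_rank: int
    contacts: list[ContactRecord]
    filtered_contacts: list[ContactRecord]

    @property
    def interface_mean_plddt(self) -> float | None:
        """Mean pLDDT over residues of the filtered contacts (or None)."""
        return self._mean_plddt

    _mean_plddt: float | None = field(default=None, repr=False)


@dataclass
class ScreenResult:
    pair_label: tuple[str, str]
    interface_ab: InterfaceSet | None
    interface_ba: InterfaceSet | None
    consensus: bool
    score: float
    evaluable: bool = True


def _chain_heavy_arrays(model: StructureModel, chain_id: str):
    """Coordinates + residue bookkeeping for the heavy atoms of one chain."""
    chain = model.chain(chain_id)
    coords: list[list[float]] = []
    res_of_atom: list[int] = []
    residues = []
    for ri, res in enumerate(chain.residues):
        heavy = res.heavy_atoms()
        for a in heavy:
            coords.append([a.x, a.y, a.z])
            res_of_atom.append(ri)
        residues.append(res)
    if not coords:
        raise ValueError(f"chain {chain_id}: no non-hydrogen atoms")
    return np.asarray(coords, float), np.asarray(res_of_atom), residues


def extract_contacts(
    model: StructureModel,
    chain_pair: tuple[str, str],
    cutoff_angstrom: float = 4.0,
) -> list[ContactRecord]:
    """Residue pairs of two chains with min heavy-atom distance <= cutoff.

    Each contacting residue pair is reported once with its minimum distance,
    ordered by (res_a_index, res_b_index).  A k-d tree prunes the candidate
    atom pairs; the inclusion decision itself uses the plain squared-distance
    comparison, so results are bit-identical to a brute-force scan.
    """
    if cutoff_angstrom <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_angstrom}")
    cid_a, cid_b = chain_pair
    if cid_a == cid_b:
        raise ValueError("chain pair must name two distinct chains")
    xyz_a, res_a, residues_a = _chain_heavy_arrays(model, cid_a)
    xyz_b, res_b, residues_b = _chain_heavy_arrays(model, cid_b)

    # slack on the tree query guards against ulp differences at the boundary;
    # the <= comparison below is authoritative
    tree_b = cKDTree(xyz_b)
    candidates = tree_b.query_ball_point(xyz_a, cutoff_angstrom * (1 + 1e-9))
    cutoff_sq = cutoff_angstrom * cutoff_angstrom

    best: dict[tuple[int, int], float] = {}
    for ia, hits in enumerate(candidates):
        if not hits:
            continue
        d2 = np.sum((xyz_b[hits] - xyz_a[ia]) ** 2, axis=1)
        for ib, dd in zip(hits, d2):
            if dd <= cutoff_sq:
                key = (int(res_a[ia]), int(res_b[ib]))
                if dd < best.get(key, np.inf):
                    best[key] = float(dd)

    records = []
    for (ri, rj) in sorted(best, key=lambda k: (residues_a[k[0]].seq_index, residues_b[k[1]].seq_index)):
        ra, rb = residues_a[ri], residues_b[rj]
        records.append(
            ContactRecord(
                chain_a_id=cid_a,
                res_a_index=ra.seq_index,
                res_a_name=ra.name,
                chain_b_id=cid_b,
                res_b_index=rb.seq_index,
                res_b_name=rb.name,
                min_distance=float(np.sqrt(best[(ri, rj)])),
            )
        )
    return records


def filter_by_plddt(
    contacts: Sequence[ContactRecord],
    model: StructureModel,
    min_plddt: float = 50.0,
    scope: str = "both",
) -> list[ContactRecord]:
    """Drop contacts whose partner residues fall below the confidence floor.

    ``scope="both"`` (default) keeps a contact only when *both* residues have
    pLDDT >= ``min_plddt``; ``scope="either"`` keeps it when at least one
    does.  The boundary is inclusive: a residue at exactly the floor passes.
    """
    if scope not in ("both", "either"):
        raise ValueError(f"scope must be 'both' or 'either', got {scope!r}")
    kept = []
    for c in contacts:
        pa = model.residue(c.chain_a_id, c.res_a_index).plddt
        pb = model.residue(c.chain_b_id, c.res_b_index).plddt
        ok = (pa >= min_plddt and pb >= min_plddt) if scope == "both" else (
            pa >= min_plddt or pb >= min_plddt
        )
        if ok:
            kept.append(c)
    return kept


def rank_models(models: Sequence[StructureModel]) -> list[StructureModel]:
    """Order models by mean pLDDT (descending) and assign rank 1..n.

    Ties break deterministically by model_id.
    """
    if not models:
        raise ValueError("need at least one model to rank")
    ordered = sorted(models, key=lambda m: (-m.mean_plddt, m.model_id))
    for i, m in enumerate(ordered, start=1):
        m.rank = i
    return ordered


def _interface_mean_plddt(
    contacts: Sequence[ContactRecord], model: StructureModel
) -> float | None:
    residues = set()
    for c in contacts:
        residues.add((c.chain_a_id, c.res_a_index))
        residues.add((c.chain_b_id, c.res_b_index))
    if not residues:
        return None
    return float(np.mean([model.residue(cid, ri).plddt for cid, ri in residues]))


def build_interface_set(
    model: StructureModel,
    chain_pair: tuple[str, str],
    order_tag: str,
    pair_label: tuple[str, str],
    cutoff_angstrom: float = 4.0,
    min_plddt: float = 50.0,
    filter_scope: str = "both",
) -> InterfaceSet:
    """Extract + filter contacts of one ordered model into an InterfaceSet."""
    contacts = extract_contacts(model, chain_pair, cutoff_angstrom)
    filtered = filter_by_plddt(contacts, model, min_plddt, scope=filter_scope)
    iset = InterfaceSet(
        pair_label=tuple(sorted(pair_label)),
        order_tag=order_tag,
        model_rank=model.rank if model.rank is not None else 1,
        contacts=contacts,
        filtered_contacts=filtered,
    )
    iset._mean_plddt = _interface_mean_plddt(filtered, model)
    return iset


def evaluate_pair(
    interface_ab: InterfaceSet,
    interface_ba: InterfaceSet,
    min_contacts: int = 1,
) -> ScreenResult:
    """Bidirectional consensus: both input orders must show the interface.

    The ranking score is the minimum over the two orders of the interface
    mean pLDDT (an empty interface scores 0), a conservative consensus key.
    """
    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    if interface_ab.pair_label != interface_ba.pair_label:
        raise ValueError(
            f"mismatched pair labels: {interface_ab.pair_label} vs "
            f"{interface_ba.pair_label}"
        )
    consensus = (
        len(interface_ab.filtered_contacts) >= min_contacts
        and len(interface_ba.filtered_contacts) >= min_contacts
    )
    scores = []
    for iset in (interface_ab, interface_ba):
        m = iset.interface_mean_plddt
        scores.append(0.0 if m is None else m)
    return ScreenResult(
        pair_label=interface_ab.pair_label,
        interface_ab=interface_ab,
        interface_ba=interface_ba,
        consensus=consensus,
        score=float(min(scores)),
    )


def screen_all_pairs(
    models_by_ordered_pair: Mapping[tuple[str, str], Sequence[StructureModel]],
    cutoff_angstrom: float = 4.0,
    min_plddt: float = 50.0,
    min_contacts: int = 1,
    filter_scope: str = "both",
) -> list[ScreenResult]:
    """Run the consensus screen over every subunit pair.

    ``models_by_ordered_pair`` maps an *ordered* (first_subunit,
    second_subunit) input to its ranked candidate models; chains are assumed
    labelled 'A' (first input) and 'B' (second).  For each unordered pair the
    rank-1 model of each order is evaluated.  Pairs missing one order are
    reported non-evaluable with a warning, and the run continues.

    Results are sorted consensus-first, then by descending score, then by
    label for determinism.
    """
    unordered: dict[tuple[str, str], dict[tuple[str, str], Sequence[StructureModel]]] = {}
    for order, models in models_by_ordered_pair.items():
        key = tuple(sorted(order))
        unordered.setdefault(key, {})[order] = models

    results: list[ScreenResult] = []
    for label in sorted(unordered):
        orders = unordered[label]
        if len(orders) < 2:
            warnings.warn(
                f"pair {label}: only one input order present; marked non-evaluable",
                stacklevel=2,
            )
            results.append(
                ScreenResult(
                    pair_label=label,
                    interface_ab=None,
                    interface_ba=None,
                    consensus=False,
                    score=0.0,
                    evaluable=False,
                )
            )
            continue
        isets = []
        for order in sorted(orders):
            ranked = rank_models(list(orders[order]))
            top = ranked[0]
            isets.append(
                build_interface_set(
                    top,
                    ("A", "B"),
                    order_tag=f"{order[0]}:{order[1]}",
                    pair_label=label,
                    cutoff_angstrom=cutoff_angstrom,
                    min_plddt=min_plddt,
                    filter_scope=filter_scope,
                )
            )
        results.append(evaluate_pair(isets[0], isets[1], min_contacts=min_contacts))

    results.sort(key=lambda r: (not r.consensus, -r.score, r.pair_label))
    return results


def screen_report(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results to one row per (pair, order) for TSV export."""
    rows = []
    for r in results:
        if not r.evaluable:
            rows.append(
                {
                    "pair": "-".join(r.pair_label),
                    "order": "NA",
                    "n_contacts": 0,
                    "n_filtered": 0,
                    "interface_mean_plddt": np.nan,
                    "consensus": False,
                    "evaluable": False,
                    "score": 0.0,
                }
            )
            continue
        for iset in (r.interface_ab, r.interface_ba):
            m = iset.interface_mean_plddt
            rows.append(
                {
                    "pair": "-".join(r.pair_label),
                    "order": iset.order_tag,
                    "n_contacts": len(iset.contacts),
                    "n_filtered": len(iset.filtered_contacts),
                    "interface_mean_plddt": np.nan if m is None else round(m, 4),
                    "consensus": r.consensus,
                    "evaluable": True,
                    "score": round(r.score, 4),
                }
            )
    return pd.DataFrame(rows)
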