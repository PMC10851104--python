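"""Representative nucleosome complexes, binding modes and hotspot profiles.

Representative selection applies, in order: drop subnucleosomal structures
(fewer than 7 of the 8 core-histone chains), drop structures where more
than 20 bp of nucleosomal DNA lost all 5 Å heavy-atom contact with the
octamer, drop partners shorter than 10 residues, then group the remaining
candidates per partner and merge structures with near-identical interfaces
(interface-residue Jaccard >= 0.8 on consensus coordinates means the same
binding mode), keeping the highest-resolution mutation-free member.  A
partner with genuinely distinct binding modes keeps one structure per mode.

Binding modes partition contacting partners into three classes: dna_only
(DPI contacts and no HPI), histone_only (HPI and no DPI) and both.

Hotspots are profiled on two axes: histone consensus positions (alignment
columns of a per-type multiple sequence alignment of variants) and DNA
base pairs indexed relative to the dyad (10 bp per superhelic location).
Per position the profile counts distinct partner proteins — a partner
touching through two of its chains counts once — and the mean heavy-atom
contact count over (structure, partner) pairs with at least one contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from histonet.exceptions import (
    HistonetError,
    MissingResolutionError,
    StrandMismatchError,
    VariantMissingError,
)
from histonet.interfaces import InterfaceExtraction, extract_interfaces
from histonet.structure_io import HistoneAnnotation, Structure

logger = logging.getLogger(__name__)

MODES = ("dna_only", "histone_only", "both")


# ---------------------------------------------------------------------------
# metadata & representative selection

@dataclass
class PartnerInfo:
    partner_id: str
    length: int
    interface: frozenset  # interface residues in consensus/sequence coords


@dataclass
class ComplexMetadata:
    structure_id: str
    resolution: float | None
    has_mutations: bool
    core_histone_count: int       # of 8 core-histone chains present
    n_unanchored_bp: int          # bp of DNA with no 5 Å octamer contact
    dna_length: int
    partners: list[PartnerInfo] = field(default_factory=list)


@dataclass
class SelectionResult:
    selected: set
    kept_pairs: list            # (structure_id, partner_id)
    dropped: dict               # reason -> list of ids


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def select_representatives(
    metadata: list[ComplexMetadata],
    redundancy_jaccard: float = 0.8,
    min_core_histones: int = 7,
    max_unanchored_bp: int = 20,
    min_partner_length: int = 10,
) -> SelectionResult:
    """Pick one representative structure per partner binding mode.

    Raises :class:`MissingResolutionError` when a redundancy group with
    more than one member must be arbitrated but a member lacks resolution.
    """
    dropped: dict[str, list] = {
        "subnucleosomal": [], "unanchored_dna": [], "short_partner": [],
        "redundant": [],
    }
    survivors: list[ComplexMetadata] = []
    for m in metadata:
        if m.core_histone_count < min_core_histones:
            dropped["subnucleosomal"].append(m.structure_id)
        elif m.n_unanchored_bp > max_unanchored_bp:
            dropped["unanchored_dna"].append(m.structure_id)
        else:
            survivors.append(m)

    groups: dict[str, list[tuple[ComplexMetadata, PartnerInfo]]] = {}
    for m in survivors:
        for p in m.partners:
            if p.length < min_partner_length:
                dropped["short_partner"].append((m.structure_id, p.partner_id))
                continue
            groups.setdefault(p.partner_id, []).append((m, p))

    kept_pairs: list[tuple[str, str]] = []
    selected: set = set()
    for partner_id in sorted(groups):
        members = sorted(groups[partner_id], key=lambda mp: mp[0].structure_id)
        clusters: list[list[tuple[ComplexMetadata, PartnerInfo]]] = []
        for m, p in members:
            placed = False
            for cluster in clusters:
                if any(
                    jaccard(p.interface, q.interface) >= redundancy_jaccard
                    for _, q in cluster
                ):
                    cluster.append((m, p))
                    placed = True
                    break
            if not placed:
                clusters.append([(m, p)])
        for cluster in clusters:
            if len(cluster) > 1:
                missing = [m.structure_id for m, _ in cluster if m.resolution is None]
                if missing:
                    raise MissingResolutionError(
                        f"partner {partner_id}: structures lacking resolution "
                        f"in a contested redundancy group: {missing}"
                    )
            best = min(
                cluster,
                key=lambda mp: (
                    mp[0].has_mutations,
                    mp[0].resolution if mp[0].resolution is not None else 0.0,
                    mp[0].structure_id,
                ),
            )
            kept_pairs.append((best[0].structure_id, partner_id))
            selected.add(best[0].structure_id)
            for m, _ in cluster:
                if m.structure_id != best[0].structure_id:
                    dropped["redundant"].append((m.structure_id, partner_id))
    return SelectionResult(selected=selected, kept_pairs=kept_pairs, dropped=dropped)


def build_complex_metadata(
    structure: Structure,
    annotations: list[HistoneAnnotation] | dict,
    extraction: InterfaceExtraction,
    resolution: float | None = None,
    has_mutations: bool = False,
    core_types: tuple = ("H2A", "H2B", "H3", "H4"),
) -> ComplexMetadata:
    """Derive selection metadata from a parsed complex and its interfaces."""
    ann = annotations if isinstance(annotations, dict) else {
        a.chain_id: a for a in annotations
    }
    core_count = sum(
        1 for a in ann.values() if a.role == "histone" and a.histone_type in core_types
    )
    dna_chains = [c for c in structure.chains if ann[c.chain_id].role == "dna"]
    dna_len = max((len(c.residues) for c in dna_chains), default=0)

    # bp anchored to the octamer: DNA residues with an HDI contact
    anchored: set[tuple[str, int]] = set()
    for e in extraction.edges:
        if e.interaction_class != "HDI":
            continue
        for node_class, cid, rid in (
            (e.node_class_a, e.chain_a, e.resid_a),
            (e.node_class_b, e.chain_b, e.resid_b),
        ):
            if node_class == "dna":
                anchored.add((cid, rid))
    unanchored = 0
    for chain in dna_chains:
        unanchored_strand = sum(
            1 for r in chain.residues if (chain.chain_id, r.seq_id) not in anchored
        )
        unanchored = max(unanchored, unanchored_strand)

    partner_proteins: dict[str, PartnerInfo] = {}
    chain_protein: dict[str, str] = {}
    for e in extraction.edges:
        chain_protein[e.chain_a] = e.protein_a
        chain_protein[e.chain_b] = e.protein_b
    for chain in structure.chains:
        a = ann[chain.chain_id]
        if a.role != "partner":
            continue
        pid = chain_protein.get(chain.chain_id)
        if pid is None:
            from histonet.interfaces import protein_node_id
            pid = protein_node_id(chain, a)
        info = partner_proteins.setdefault(pid, PartnerInfo(pid, 0, frozenset()))
        info.length = max(info.length, len(chain.residues))
    # partner interface residues (HPI histone side + DPI dna side), sequence coords
    iface: dict[str, set] = {pid: set() for pid in partner_proteins}
    for e in extraction.edges:
        if e.interaction_class not in ("HPI", "DPI"):
            continue
        for me, other in ((("a"), ("b")), (("b"), ("a"))):
            pid = getattr(e, f"protein_{me}")
            if getattr(e, f"node_class_{me}") == "partner" and pid in iface:
                opos = getattr(e, f"seq_pos_{other}")
                ochain = getattr(e, f"chain_{other}")
                orid = getattr(e, f"resid_{other}")
                iface[pid].add((ochain, opos if opos is not None else orid))
    for pid, info in partner_proteins.items():
        info.interface = frozenset(iface[pid])
    return ComplexMetadata(
        structure_id=structure.structure_id,
        resolution=resolution,
        has_mutations=has_mutations,
        core_histone_count=core_count,
        n_unanchored_bp=unanchored,
        dna_length=dna_len,
        partners=list(partner_proteins.values()),
    )


# ---------------------------------------------------------------------------
# binding modes

@dataclass(frozen=True)
class BindingModeLabel:
    structure_id: str
    partner_id: str
    mode: str  # dna_only | histone_only | both | none


def classify_binding_modes(
    structure: Structure,
    annotations: list[HistoneAnnotation] | dict,
    extraction: InterfaceExtraction | None = None,
    cutoff: float = 5.0,
) -> list[BindingModeLabel]:
    """Label every partner protein by which interface sets are non-empty."""
    ann = annotations if isinstance(annotations, dict) else {
        a.chain_id: a for a in annotations
    }
    if extraction is None:
        extraction = extract_interfaces(structure, ann, cutoff=cutoff)
    from histonet.interfaces import protein_node_id

    partner_ids = set()
    for chain in structure.chains:
        if ann[chain.chain_id].role == "partner":
            partner_ids.add(protein_node_id(chain, ann[chain.chain_id]))
    has_hpi: set = set()
    has_dpi: set = set()
    for e in extraction.edges:
        for side in ("a", "b"):
            if getattr(e, f"node_class_{side}") == "partner":
                pid = getattr(e, f"protein_{side}")
                if e.interaction_class == "HPI":
                    has_hpi.add(pid)
                elif e.interaction_class == "DPI":
                    has_dpi.add(pid)
    labels = []
    for pid in sorted(partner_ids):
        if pid in has_hpi and pid in has_dpi:
            mode = "both"
        elif pid in has_hpi:
            mode = "histone_only"
        elif pid in has_dpi:
            mode = "dna_only"
        else:
            mode = "none"
            logger.warning(
                "partner %s has no contacts in %s; excluded from mode statistics",
                pid, structure.structure_id,
            )
        labels.append(BindingModeLabel(structure.structure_id, pid, mode))
    return labels


def mode_fractions(labels: list[BindingModeLabel]) -> dict[str, float]:
    """Fractions of dna_only/histone_only/both among contacting partners."""
    contacting = [lb for lb in labels if lb.mode != "none"]
    n = len(contacting)
    return {
        mode: (sum(1 for lb in contacting if lb.mode == mode) / n if n else 0.0)
        for mode in MODES
    }


# ---------------------------------------------------------------------------
# consensus mapping

def load_alignment(path: str | Path):
    """Aligned FASTA -> Bio.Align.MultipleSeqAlignment."""
    return AlignIO.read(str(path), "fasta")


def consensus_position(alignment, variant_id: str, position: int) -> int:
    """Alignment column (1-based) of the variant's ungapped position."""
    row = None
    for rec in alignment:
        if rec.id == variant_id:
            row = str(rec.seq)
            break
    if row is None:
        raise VariantMissingError(
            f"variant {variant_id!r} absent from the alignment"
        )
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch not in ("-", "."):
            count += 1
            if count == position:
                return col
    raise HistonetError(
        f"position {position} beyond the aligned length of {variant_id!r}"
    )


def map_to_consensus(
    residues: list[tuple[str, int]],
    alignment,
) -> list[tuple[str, int, int]]:
    """Map (variant_id, ungapped position) pairs to alignment columns."""
    return [
        (vid, pos, consensus_position(alignment, vid, pos))
        for vid, pos in residues
    ]


# ---------------------------------------------------------------------------
# hotspot profiling

@dataclass(frozen=True)
class ConsensusContact:
    structure_id: str
    partner_id: str
    histone_type: str
    consensus_pos: int
    n_atom_contacts: int


def consensus_contacts(
    extraction: InterfaceExtraction,
    alignments: dict[str, object],
) -> list[ConsensusContact]:
    """HPI edges mapped to (histone type, consensus position) records.

    ``alignments`` maps histone type (H1/H2A/H2B/H3/H4) to the aligned
    variants of that type; the histone side's protein id must name a row.
    """
    records = []
    for e in extraction.edges:
        if e.interaction_class != "HPI":
            continue
        if e.node_class_a.startswith("histone"):
            htype = e.node_class_a.split(":", 1)[1]
            variant, pos, partner = e.protein_a, e.seq_pos_a, e.protein_b
        else:
            htype = e.node_class_b.split(":", 1)[1]
            variant, pos, partner = e.protein_b, e.seq_pos_b, e.protein_a
        if pos is None:
            continue
        aln = alignments.get(htype)
        if aln is None:
            raise VariantMissingError(f"no alignment supplied for type {htype}")
        col = consensus_position(aln, variant, pos)
        records.append(
            ConsensusContact(
                structure_id=e.structure_id, partner_id=partner,
                histone_type=htype, consensus_pos=col,
                n_atom_contacts=e.n_atom_contacts,
            )
        )
    return records


def profile_histone_hotspots(
    records: list[ConsensusContact],
    alignments: dict[str, object],
) -> pd.DataFrame:
    """Per (histone type, consensus position): distinct-partner count and
    mean heavy-atom contacts over contacting (structure, partner) pairs.

    Untouched positions appear with zeros.
    """
    partners: dict[tuple, set] = {}
    pair_contacts: dict[tuple, dict[tuple, int]] = {}
    for r in records:
        key = (r.histone_type, r.consensus_pos)
        partners.setdefault(key, set()).add(r.partner_id)
        per_pair = pair_contacts.setdefault(key, {})
        pair = (r.structure_id, r.partner_id)
        per_pair[pair] = per_pair.get(pair, 0) + r.n_atom_contacts
    rows = []
    for htype, aln in sorted(alignments.items()):
        ncol = aln.get_alignment_length()
        for pos in range(1, ncol + 1):
            key = (htype, pos)
            pairs = pair_contacts.get(key, {})
            rows.append(
                {
                    "axis": "histone_consensus",
                    "histone_type": htype,
                    "position": pos,
                    "unique_partners": len(partners.get(key, ())),
                    "mean_contacts": float(np.mean(list(pairs.values()))) if pairs else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BpContact:
    structure_id: str
    partner_id: str
    bp_rel: int           # base pair index relative to the dyad
    n_atom_contacts: int


def dna_bp_contacts(
    structure: Structure,
    annotations: list[HistoneAnnotation] | dict,
    extraction: InterfaceExtraction,
    dyad: int | None = None,
    pair_tolerance: int = 4,
) -> tuple[list[BpContact], tuple[int, int]]:
    """DPI contacts per DNA base pair, dyad-relative.

    Strands are paired by reverse indexing (position i on strand I pairs
    with position n−i+1 on strand II); a partner touching both strands of
    one pair counts once.  The dyad defaults to the midpoint base pair
    ((n+1)//2).  Returns the records and the (min, max) dyad-relative bp
    range covered by the structure.
    """
    ann = annotations if isinstance(annotations, dict) else {
        a.chain_id: a for a in annotations
    }
    dna_chains = sorted(
        (c for c in structure.chains if ann[c.chain_id].role == "dna"),
        key=lambda c: c.chain_id,
    )
    if not dna_chains:
        return [], (0, 0)
    if len(dna_chains) != 2:
        raise StrandMismatchError(
            f"{structure.structure_id}: expected 2 DNA strands, "
            f"found {len(dna_chains)}"
        )
    s1, s2 = dna_chains
    n1, n2 = len(s1.residues), len(s2.residues)
    if abs(n1 - n2) > pair_tolerance:
        raise StrandMismatchError(
            f"{structure.structure_id}: strand lengths {n1} vs {n2} differ "
            f"by more than {pair_tolerance} nt"
        )
    n = max(n1, n2)
    if dyad is None:
        dyad = (n + 1) // 2
    ordinal = {}
    for chain, reverse in ((s1, False), (s2, True)):
        for idx, res in enumerate(
            sorted(chain.residues, key=lambda r: r.seq_id), start=1
        ):
            bp = (n - idx + 1) if reverse else idx
            ordinal[(chain.chain_id, res.seq_id)] = bp

    agg: dict[tuple, int] = {}
    for e in extraction.edges:
        if e.interaction_class != "DPI":
            continue
        if e.node_class_a == "dna":
            dna_key = (e.chain_a, e.resid_a)
            partner = e.protein_b
        else:
            dna_key = (e.chain_b, e.resid_b)
            partner = e.protein_a
        bp = ordinal.get(dna_key)
        if bp is None:
            continue
        key = (e.structure_id, partner, bp - dyad)
        agg[key] = agg.get(key, 0) + e.n_atom_contacts
    records = [
        BpContact(sid, pid, rel, count)
        for (sid, pid, rel), count in sorted(agg.items())
    ]
    return records, (1 - dyad, n - dyad)


def profile_dna_hotspots(
    records: list[BpContact],
    bp_range: tuple[int, int],
) -> pd.DataFrame:
    """Per dyad-relative base pair: distinct-partner count, mean contacts, SHL."""
    partners: dict[int, set] = {}
    pair_contacts: dict[int, dict[tuple, int]] = {}
    for r in records:
        partners.setdefault(r.bp_rel, set()).add(r.partner_id)
        per_pair = pair_contacts.setdefault(r.bp_rel, {})
        pair = (r.structure_id, r.partner_id)
        per_pair[pair] = per_pair.get(pair, 0) + r.n_atom_contacts
    rows = []
    for bp in range(bp_range[0], bp_range[1] + 1):
        pairs = pair_contacts.get(bp, {})
        rows.append(
            {
                "axis": "dna_bp",
                "position": bp,
                "shl": int(round(bp / 10)),
                "unique_partners": len(partners.get(bp, ())),
                "mean_contacts": float(np.mean(list(pairs.values()))) if pairs else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional-class comparison

def compare_modes_by_function(
    records: list[ConsensusContact],
    functional_classes: dict[str, str],
) -> dict[str, dict]:
    """Per functional class: contacted consensus positions, with positions
    contacted by >= 2 distinct partners flagged as shared.

    Structures absent from the annotation table group under "unclassified"
    with a warning.
    """
    by_class: dict[str, dict] = {}
    for r in records:
        cls = functional_classes.get(r.structure_id)
        if cls is None:
            logger.warning(
                "structure %s lacks a functional class; grouped as unclassified",
                r.structure_id,
            )
            cls = "unclassified"
        entry = by_class.setdefault(
            cls, {"positions": set(), "partners_at": {}}
        )
        key = (r.histone_type, r.consensus_pos)
        entry["positions"].add(key)
        entry["partners_at"].setdefault(key, set()).add(r.partner_id)
    out = {}
    for cls, entry in by_class.items():
        shared = {
            key for key, parts in entry["partners_at"].items() if len(parts) >= 2
        }
        out[cls] = {"positions": entry["positions"], "shared_positions": shared}
    return out
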