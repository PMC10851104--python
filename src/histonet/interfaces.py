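"""Heavy-atom contact detection and interaction-class assignment.

A residue pair on two different chains is in contact when any pair of their
heavy (non-hydrogen) atoms lies within the cutoff, 5.0 Å inclusive by
default.  Contacts are classified by the chain roles into the four
interaction classes used throughout the pipeline:

====  =======================================
HHI   histone–histone
HDI   histone–DNA
HPI   histone–partner (non-histone protein)
DPI   DNA–partner
====  =======================================

Partner–partner (PPI) and DNA–DNA (DDI) contacts are computed and recorded
but excluded from the four-class networks.  Contacts involving modified
histone residues (ALY, M3L, KCR, ...) are additionally tagged with their
PTM type so PTM-site interactions can be counted per type and per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from histonet import config as _config
from histonet.exceptions import HistonetError
from histonet.structure_io import HistoneAnnotation, Structure

logger = logging.getLogger(__name__)

FOUR_CLASSES = ("HHI", "HDI", "HPI", "DPI")


@dataclass(frozen=True)
class ContactPair:
    """Residue-level inter-chain contact (canonically ordered endpoints)."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    min_distance: float
    atom_contact_count: int


@dataclass
class InterfaceResidue:
    chain_id: str
    residue_seq_id: int
    residue_name: str
    role: str
    sequence_position: int | None = None
    histone_type: str | None = None
    ptm_type: str | None = None


@dataclass
class ResidueContactEdge:
    """Classified residue-level interaction edge, ready for network assembly."""

    structure_id: str
    interaction_class: str  # HHI | HDI | HPI | DPI | PPI | DDI
    chain_a: str
    resid_a: int
    resname_a: str
    seq_pos_a: int | None
    protein_a: str          # protein-level node id of side a
    node_class_a: str       # histone:<type> | partner | dna
    chain_b: str
    resid_b: int
    resname_b: str
    seq_pos_b: int | None
    protein_b: str
    node_class_b: str
    min_dist: float
    n_atom_contacts: int
    ptm_type: str | None = None


@dataclass
class InterfaceExtraction:
    structure_id: str
    edges: list[ResidueContactEdge] = field(default_factory=list)
    interface_residues: dict[str, list[InterfaceResidue]] = field(default_factory=dict)

    def edges_of_class(self, interaction_class: str) -> list[ResidueContactEdge]:
        return [e for e in self.edges if e.interaction_class == interaction_class]


def _heavy_atom_table(structure: Structure):
    """Stack heavy atoms into arrays: positions, chain index, residue seq id."""
    positions, chain_idx, res_ids = [], [], []
    for ci, chain in enumerate(structure.chains):
        for res in chain.residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    positions.append(atom.position)
                    chain_idx.append(ci)
                    res_ids.append(res.seq_id)
    if not positions:
        return np.empty((0, 3)), np.array([], int), np.array([], int)
    return np.asarray(positions), np.asarray(chain_idx), np.asarray(res_ids)


def find_contacts(structure: Structure, cutoff: float = 5.0) -> list[ContactPair]:
    """All inter-chain residue contacts at the heavy-atom distance cutoff.

    Uses a k-d tree over all heavy atoms; results are identical to the
    all-pairs scan (the cutoff comparison is inclusive).  Intra-chain pairs
    are never reported.  A single-chain structure yields an empty list with
    a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(structure.chains) < 2:
        logger.warning(
            "structure %s has a single chain; no inter-chain contacts",
            structure.structure_id,
        )
        return []
    pos, chain_idx, res_ids = _heavy_atom_table(structure)
    if len(pos) == 0:
        return []
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    chain_names = [ch.chain_id for ch in structure.chains]

    best: dict[tuple, tuple[float, int]] = {}
    for i, j in pairs:
        ci, cj = chain_idx[i], chain_idx[j]
        if ci == cj:
            continue
        key_i = (chain_names[ci], int(res_ids[i]))
        key_j = (chain_names[cj], int(res_ids[j]))
        key = (key_i, key_j) if key_i <= key_j else (key_j, key_i)
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d > cutoff:  # query_pairs is inclusive of r, but guard anyway
            continue
        cur = best.get(key)
        if cur is None:
            best[key] = (d, 1)
        else:
            best[key] = (min(cur[0], d), cur[1] + 1)

    out = [
        ContactPair(a[0], a[1], b[0], b[1], d, n)
        for (a, b), (d, n) in best.items()
    ]
    out.sort(key=lambda c: (c.chain_a, c.residue_a, c.chain_b, c.residue_b))
    return out


def classify_contact(
    contact: ContactPair,
    annotations: dict[str, HistoneAnnotation] | list[HistoneAnnotation],
) -> str:
    """Map a contact to HHI/HDI/HPI/DPI (or PPI/DDI, excluded downstream)."""
    ann = _as_annotation_map(annotations)
    try:
        role_a = ann[contact.chain_a].role
        role_b = ann[contact.chain_b].role
    except KeyError as exc:
        raise HistonetError(f"chain {exc.args[0]!r} has no annotation") from exc
    roles = frozenset((role_a, role_b))
    if roles == {"histone"}:
        return "HHI"
    if roles == {"histone", "dna"}:
        return "HDI"
    if roles == {"histone", "partner"}:
        return "HPI"
    if roles == {"partner", "dna"}:
        return "DPI"
    if roles == {"partner"}:
        return "PPI"
    return "DDI"


def _as_annotation_map(annotations) -> dict[str, HistoneAnnotation]:
    if isinstance(annotations, dict):
        return annotations
    return {a.chain_id: a for a in annotations}


def _slugify(text: str) -> str:
    return "".join(c if c.isalnum() or c in ".-" else "_" for c in text).strip("_")


def protein_node_id(chain, annotation: HistoneAnnotation) -> str:
    """Protein-level node id: UniProt id when known, else entity-name slug."""
    if chain.uniprot_id:
        return chain.uniprot_id
    if chain.entity_name:
        return _slugify(chain.entity_name)
    if annotation.role == "dna":
        return "DNA"
    return f"chain_{chain.chain_id}"


def _node_class(annotation: HistoneAnnotation) -> str:
    if annotation.role == "histone":
        return f"histone:{annotation.histone_type}"
    return annotation.role


def extract_interfaces(
    structure: Structure,
    annotations: dict[str, HistoneAnnotation] | list[HistoneAnnotation],
    ptm_map: dict[str, str] | None = None,
    cutoff: float = 5.0,
) -> InterfaceExtraction:
    """Classified residue-level interaction edges plus per-class interface sets.

    Every contact becomes a :class:`ResidueContactEdge` carrying structure
    provenance and protein-level node ids for both endpoints; the interface
    residue sets of each class are the unions of residues appearing in that
    class's contacts.  HPI edges touching a modified histone residue carry
    its PTM type.
    """
    ann = _as_annotation_map(annotations)
    ptm = ptm_map if ptm_map is not None else _config.load_ptm_map()
    contacts = find_contacts(structure, cutoff=cutoff)
    chains = {ch.chain_id: ch for ch in structure.chains}

    extraction = InterfaceExtraction(structure_id=structure.structure_id)
    iface: dict[str, dict[tuple[str, int], InterfaceResidue]] = {
        c: {} for c in FOUR_CLASSES
    }
    for contact in contacts:
        cls = classify_contact(contact, ann)
        side = {}
        for tag, (cid, rid) in (
            ("a", (contact.chain_a, contact.residue_a)),
            ("b", (contact.chain_b, contact.residue_b)),
        ):
            chain = chains[cid]
            res = chain.residue(rid)
            side[tag] = (cid, rid, res, chain, ann[cid])
        ptm_type = None
        for cid, rid, res, chain, a in side.values():
            if a.role == "histone" and res.name in ptm:
                ptm_type = ptm[res.name]
        edge = ResidueContactEdge(
            structure_id=structure.structure_id,
            interaction_class=cls,
            chain_a=side["a"][0],
            resid_a=side["a"][1],
            resname_a=side["a"][2].name,
            seq_pos_a=side["a"][2].sequence_position,
            protein_a=protein_node_id(side["a"][3], side["a"][4]),
            node_class_a=_node_class(side["a"][4]),
            chain_b=side["b"][0],
            resid_b=side["b"][1],
            resname_b=side["b"][2].name,
            seq_pos_b=side["b"][2].sequence_position,
            protein_b=protein_node_id(side["b"][3], side["b"][4]),
            node_class_b=_node_class(side["b"][4]),
            min_dist=contact.min_distance,
            n_atom_contacts=contact.atom_contact_count,
            ptm_type=ptm_type,
        )
        extraction.edges.append(edge)
        if cls in FOUR_CLASSES:
            for cid, rid, res, chain, a in side.values():
                key = (cid, rid)
                if key not in iface[cls]:
                    iface[cls][key] = InterfaceResidue(
                        chain_id=cid,
                        residue_seq_id=rid,
                        residue_name=res.name,
                        role=a.role,
                        sequence_position=res.sequence_position,
                        histone_type=a.histone_type,
                        ptm_type=ptm.get(res.name) if a.role == "histone" else None,
                    )
    extraction.interface_residues = {
        cls: list(d.values()) for cls, d in iface.items()
    }
    return extraction


@dataclass(frozen=True)
class PtmContact:
    structure_id: str
    ptm_chain: str
    ptm_residue: int
    ptm_type: str
    partner: str


def detect_ptm_contacts(
    edges: list[ResidueContactEdge],
    ptm_map: dict[str, str] | None = None,
) -> list[PtmContact]:
    """HPI edges whose histone residue is a mapped modified component.

    One record per (PTM site, partner protein) contact; counts per PTM type
    or per site follow by grouping.
    """
    ptm = ptm_map if ptm_map is not None else _config.load_ptm_map()
    out: list[PtmContact] = []
    for edge in edges:
        if edge.interaction_class != "HPI":
            continue
        for (cls_attr, cid, rid, rname, partner) in (
            (edge.node_class_a, edge.chain_a, edge.resid_a, edge.resname_a, edge.protein_b),
            (edge.node_class_b, edge.chain_b, edge.resid_b, edge.resname_b, edge.protein_a),
        ):
            if cls_attr.startswith("histone") and rname in ptm:
                out.append(
                    PtmContact(
                        structure_id=edge.structure_id,
                        ptm_chain=cid,
                        ptm_residue=rid,
                        ptm_type=ptm[rname],
                        partner=partner,
                    )
                )
    return out


def edges_to_table(edges: list[ResidueContactEdge]):
    """Edge list as a DataFrame matching the TSV export layout."""
    import pandas as pd

    cols = [
        "structure_id", "class", "chain_a", "resid_a", "resname_a", "seq_pos_a",
        "chain_b", "resid_b", "resname_b", "seq_pos_b", "min_dist",
        "n_atom_contacts", "ptm_type",
    ]
    rows = [
        {
            "structure_id": e.structure_id,
            "class": e.interaction_class,
            "chain_a": e.chain_a, "resid_a": e.resid_a,
            "resname_a": e.resname_a, "seq_pos_a": e.seq_pos_a,
            "chain_b": e.chain_b, "resid_b": e.resid_b,
            "resname_b": e.resname_b, "seq_pos_b": e.seq_pos_b,
            "min_dist": round(e.min_dist, 4),
            "n_atom_contacts": e.n_atom_contacts,
            "ptm_type": e.ptm_type or "",
        }
        for e in edges
    ]
    return pd.DataFrame(rows, columns=cols)
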