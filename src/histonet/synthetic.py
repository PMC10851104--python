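"""Synthetic fixtures with planted ground truth.

Every generator plants its truth explicitly and writes a machine-readable
JSON sidecar, so downstream tests consume truth files rather than
hard-coded constants.

Toy complexes are deliberately non-physical: poly-alanine backbones (and
minimal nucleotides) laid out on widely separated "home columns", with one
designated contact atom per residue (CB for amino acids, C1' for
nucleotides).  A planted contact moves the mover residue's contact atom to
an exact distance d from the target residue's contact atom along a
direction orthogonal to the layout plane, so the nearest heavy-atom
distance of the pair is exactly d; the band d ∈ [cutoff−0.5, cutoff−0.1]
plants a contact, d ∈ [cutoff+0.1, cutoff+2.0] a non-contact, and the
±0.1 Å margin around the cutoff is never used.  Geometry is verified
against a brute-force all-pairs scan before the truth file is written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from histonet.exceptions import InfeasibleSpecError

DEFAULT_CUTOFF = 5.0

# flat-in-y local residue templates: name -> (atom, element, dx, dz)
_AA_TEMPLATE = [
    ("N", "N", -1.2, -0.5),
    ("CA", "C", 0.0, 0.0),
    ("C", "C", 1.2, 0.5),
    ("O", "O", 2.3, 0.6),
]
_AA_CONTACT = ("CB", "C", 0.0, 1.5)
_NT_TEMPLATE = [
    ("P", "P", -1.2, -0.5),
    ("O5'", "O", 0.0, 0.0),
    ("N1", "N", 1.2, 0.5),
]
_NT_CONTACT = ("C1'", "C", 0.0, 1.5)

_CHAIN_SPACING = 60.0   # Å between home columns
_RES_SPACING = 8.0      # Å between residues along a column

CORE_HISTONE_LAYOUT = [
    ("A", "H3", "Histone H3.1"),
    ("B", "H4", "Histone H4"),
    ("C", "H2A", "Histone H2A type 1"),
    ("D", "H2B", "Histone H2B type 1"),
    ("E", "H3", "Histone H3.1"),
    ("F", "H4", "Histone H4"),
    ("G", "H2A", "Histone H2A type 1"),
    ("H", "H2B", "Histone H2B type 1"),
]
_PARTNER_IDS = "PQRSTUVWXYZ"


@dataclass(frozen=True)
class PlantedPair:
    """One planted (non-)contact; the mover residue's contact atom travels."""

    target_chain: str
    target_res: int
    mover_chain: str
    mover_res: int
    distance: float


@dataclass
class PartnerSpec:
    name: str
    length: int
    # planted pairs (target_chain, target_res, partner_res, distance)
    targets: list[tuple[str, int, int, float]] = field(default_factory=list)


@dataclass
class ToyComplexSpec:
    structure_id: str = "TOY1"
    n_histone_chains: int = 8
    histone_chain_length: int = 20
    dna_length: int = 30
    partners: list[PartnerSpec] = field(default_factory=list)
    # extra planted pairs among histone/DNA chains (HHI/HDI plants)
    extra_pairs: list[PlantedPair] = field(default_factory=list)
    ptm_sites: list[tuple[str, int, str]] = field(default_factory=list)
    cutoff: float = DEFAULT_CUTOFF
    seed: int = 0


def default_partner(
    name: str = "Regulatory protein RP1",
    length: int = 12,
    targets: list[tuple[str, int, int, float]] | None = None,
) -> PartnerSpec:
    return PartnerSpec(name=name, length=length, targets=targets or [])


# ---------------------------------------------------------------------------
# toy complex generation

def _chain_plan(spec: ToyComplexSpec):
    """(chain_id, role, histone_type, entity_name, length, kind) per chain."""
    plan = []
    for cid, htype, entity in CORE_HISTONE_LAYOUT[: spec.n_histone_chains]:
        plan.append((cid, "histone", htype, entity, spec.histone_chain_length, "aa"))
    if spec.dna_length > 0:
        plan.append(("I", "dna", None, "DNA strand I", spec.dna_length, "nt"))
        plan.append(("J", "dna", None, "DNA strand J", spec.dna_length, "nt"))
    for k, partner in enumerate(spec.partners):
        if k >= len(_PARTNER_IDS):
            raise InfeasibleSpecError("too many partner chains for PDB chain ids")
        plan.append((_PARTNER_IDS[k], "partner", None, partner.name,
                     partner.length, "aa"))
    return plan


def _residue_name(kind: str, role: str, chain_id: str, res_id: int,
                  ptm: dict) -> str:
    if kind == "aa":
        return ptm.get((chain_id, res_id), "ALA")
    # alternating complementary strands
    if chain_id == "I":
        return "DA" if res_id % 2 else "DT"
    return "DT" if res_id % 2 else "DA"


def _build_atoms(spec: ToyComplexSpec, rng: np.ndarray, jitter: float):
    """Lay out all atoms; returns list of atom tuples and planted pairs."""
    plan = _chain_plan(spec)
    ptm = {(c, r): comp for c, r, comp in spec.ptm_sites}
    roles = {cid: (role, htype, entity) for cid, role, htype, entity, _, _ in plan}

    pairs: list[PlantedPair] = list(spec.extra_pairs)
    for k, partner in enumerate(spec.partners):
        pcid = _PARTNER_IDS[k]
        for (tchain, tres, pres, dist) in partner.targets:
            pairs.append(PlantedPair(tchain, tres, pcid, pres, dist))
    movers = [(p.mover_chain, p.mover_res) for p in pairs]
    if len(movers) != len(set(movers)):
        raise InfeasibleSpecError("a residue may be the mover of at most one pair")

    contact_pos: dict[tuple[str, int], np.ndarray] = {}
    home: dict[tuple[str, int], np.ndarray] = {}
    for ci, (cid, role, htype, entity, length, kind) in enumerate(plan):
        for r in range(1, length + 1):
            origin = np.array([ci * _CHAIN_SPACING, 0.0, r * _RES_SPACING])
            home[(cid, r)] = origin
            cx, cz = (_AA_CONTACT if kind == "aa" else _NT_CONTACT)[2:]
            contact_pos[(cid, r)] = origin + np.array([cx, 0.0, cz])

    # movers per target get distinct directions in the y-z plane
    per_target: dict[tuple[str, int], int] = {}
    moved_contact: dict[tuple[str, int], np.ndarray] = {}
    for p in pairs:
        tkey = (p.target_chain, p.target_res)
        mkey = (p.mover_chain, p.mover_res)
        if tkey not in contact_pos:
            raise InfeasibleSpecError(f"target residue {tkey} does not exist")
        if mkey not in contact_pos:
            raise InfeasibleSpecError(f"mover residue {mkey} does not exist")
        idx = per_target.get(tkey, 0)
        per_target[tkey] = idx + 1
        if idx > 1:
            # fan angles beyond ~25 degrees drift toward neighboring
            # residues along the column and break the exact-distance contract
            raise InfeasibleSpecError(
                f"target residue {tkey} has more than two movers"
            )
        theta = np.deg2rad(25.0) * idx + jitter
        direction = np.array([0.0, np.cos(theta), np.sin(theta)])
        moved_contact[mkey] = contact_pos[tkey] + p.distance * direction

    atoms = []  # (chain_id, res_id, res_name, atom_name, element, xyz)
    for ci, (cid, role, htype, entity, length, kind) in enumerate(plan):
        template = _AA_TEMPLATE if kind == "aa" else _NT_TEMPLATE
        contact = _AA_CONTACT if kind == "aa" else _NT_CONTACT
        for r in range(1, length + 1):
            rname = _residue_name(kind, role, cid, r, ptm)
            origin = home[(cid, r)]
            for (aname, element, dx, dz) in template:
                atoms.append(
                    (cid, r, rname, aname, element,
                     origin + np.array([dx, 0.0, dz]))
                )
            cpos = moved_contact.get((cid, r))
            if cpos is None:
                cpos = origin + np.array([contact[2], 0.0, contact[3]])
            atoms.append((cid, r, rname, contact[0], contact[1], cpos))
    return atoms, pairs, roles


def _all_pairs_residue_contacts(atoms, cutoff: float):
    """Brute-force inter-chain residue contacts: {pair: (min_dist, count)}."""
    pos = np.array([a[5] for a in atoms])
    keys = [(a[0], a[1]) for a in atoms]
    chains = np.array([a[0] for a in atoms])
    n = len(atoms)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    out: dict[tuple, tuple[float, int]] = {}
    ii, jj = np.where(dist <= cutoff)
    for i, j in zip(ii, jj):
        if i >= j or chains[i] == chains[j]:
            continue
        key = tuple(sorted((keys[i], keys[j])))
        d = float(dist[i, j])
        cur = out.get(key)
        out[key] = (d, 1) if cur is None else (min(cur[0], d), cur[1] + 1)
    return out


def _pair_class(role_a: str, role_b: str) -> str:
    roles = frozenset((role_a, role_b))
    return {
        frozenset(["histone"]): "HHI",
        frozenset(["histone", "dna"]): "HDI",
        frozenset(["histone", "partner"]): "HPI",
        frozenset(["partner", "dna"]): "DPI",
        frozenset(["partner"]): "PPI",
        frozenset(["dna"]): "DDI",
    }[roles]


def _format_pdb(spec: ToyComplexSpec, atoms, plan) -> str:
    lines = []
    fields = []
    mol_id = 0
    for cid, role, htype, entity, length, kind in plan:
        mol_id += 1
        fields.append(f"MOL_ID: {mol_id};")
        fields.append(f"MOLECULE: {entity.upper()};")
        fields.append(f"CHAIN: {cid};")
    for idx, seg in enumerate(fields, start=1):
        if idx == 1:
            lines.append(f"COMPND    {seg}")
        else:
            lines.append(f"COMPND{idx:4d} {seg}")
    serial = 0
    prev_chain = None
    for (cid, rid, rname, aname, element, xyz) in atoms:
        if prev_chain is not None and cid != prev_chain:
            lines.append("TER")
        prev_chain = cid
        serial += 1
        name_field = f" {aname:<3s}" if len(aname) < 4 else aname
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}{rname:>3s} {cid}{rid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_toy_complex(
    spec: ToyComplexSpec,
    out_dir: str | Path,
    max_tries: int = 20,
) -> tuple[Path, Path, dict]:
    """Write a toy complex PDB plus its truth sidecar.

    The truth lists every planted contact (with its interaction class) and
    non-contact; the all-pairs oracle verifies before writing that planted
    contacts are exactly the cross-chain contacts in the four classes and
    that their minimum distances equal the planted values.  Same spec and
    seed produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = _chain_plan(spec)
    last_problem = ""
    for attempt in range(max_tries):
        jitter = 0.0 if attempt == 0 else (
            np.random.default_rng(spec.seed + attempt).uniform(-0.2, 0.2)
        )
        atoms, pairs, roles = _build_atoms(spec, None, jitter)
        observed = _all_pairs_residue_contacts(atoms, spec.cutoff)
        planted_contacts = {
            tuple(sorted(((p.target_chain, p.target_res),
                          (p.mover_chain, p.mover_res)))): p.distance
            for p in pairs if p.distance <= spec.cutoff
        }
        planted_non = {
            tuple(sorted(((p.target_chain, p.target_res),
                          (p.mover_chain, p.mover_res)))): p.distance
            for p in pairs if p.distance > spec.cutoff
        }
        problem = ""
        for key, d in planted_contacts.items():
            obs = observed.get(key)
            if obs is None or abs(obs[0] - d) > 1e-6:
                problem = f"planted contact {key} not realized"
                break
        if not problem:
            for key in planted_non:
                if key in observed:
                    problem = f"planted non-contact {key} is in contact"
                    break
        if not problem:
            for key in observed:
                if key in planted_contacts:
                    continue
                cls = _pair_class(roles[key[0][0]][0], roles[key[1][0]][0])
                if cls in ("HHI", "HDI", "HPI", "DPI"):
                    problem = f"unplanned {cls} contact {key}"
                    break
        if not problem:
            break
        last_problem = problem
    else:
        raise InfeasibleSpecError(
            f"could not realize spec after {max_tries} tries: {last_problem}"
        )

    pdb_path = out_dir / f"{spec.structure_id}.pdb"
    pdb_path.write_text(_format_pdb(spec, atoms, plan))

    contacts_truth = []
    for p in pairs:
        cls = _pair_class(roles[p.target_chain][0], roles[p.mover_chain][0])
        entry = {
            "chain_a": p.target_chain, "res_a": p.target_res,
            "chain_b": p.mover_chain, "res_b": p.mover_res,
            "distance": p.distance, "class": cls,
            "is_contact": p.distance <= spec.cutoff,
        }
        contacts_truth.append(entry)
    class_counts: dict[str, int] = {}
    for entry in contacts_truth:
        if entry["is_contact"] and entry["class"] in ("HHI", "HDI", "HPI", "DPI"):
            class_counts[entry["class"]] = class_counts.get(entry["class"], 0) + 1
    incidental = [
        {"pair": [list(k[0]), list(k[1])], "min_dist": observed[k][0]}
        for k in observed
        if tuple(sorted(k)) not in planted_contacts
    ]
    truth = {
        "structure_id": spec.structure_id,
        "cutoff": spec.cutoff,
        "chains": {
            cid: {
                "role": role, "histone_type": htype,
                "entity_name": entity, "n_residues": length,
            }
            for cid, role, htype, entity, length, kind in plan
        },
        "planted_pairs": contacts_truth,
        "class_counts": class_counts,
        "n_planted_contacts": sum(1 for e in contacts_truth if e["is_contact"]),
        "incidental_excluded_contacts": incidental,
        "ptm_sites": [list(s) for s in spec.ptm_sites],
        "seed": spec.seed,
    }
    truth_path = out_dir / f"{spec.structure_id}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return pdb_path, truth_path, truth


def random_toy_spec(
    seed: int,
    structure_id: str | None = None,
    target_atoms: tuple[int, int] = (200, 2000),
) -> ToyComplexSpec:
    """Random toy complex spec with planted contacts and non-contacts,
    sized to land within the requested atom-count window."""
    rng = np.random.default_rng(seed)
    # 5 atoms per residue; choose chain lengths to hit the window
    total_atoms = int(rng.integers(*target_atoms))
    n_hist = int(rng.choice([4, 8]))
    n_partners = int(rng.integers(1, 4))
    partner_len = int(rng.integers(10, 25))
    dna_len = int(rng.integers(10, 31))
    budget = total_atoms // 5 - (2 * dna_len + n_partners * partner_len)
    hist_len = max(5, budget // n_hist)
    spec = ToyComplexSpec(
        structure_id=structure_id or f"RND{seed}",
        n_histone_chains=n_hist,
        histone_chain_length=hist_len,
        dna_length=dna_len,
        seed=seed,
    )
    hist_ids = [c for c, _, _ in CORE_HISTONE_LAYOUT[:n_hist]]
    target_use: dict[tuple, int] = {}
    for k in range(n_partners):
        n_targets = int(rng.integers(1, 5))
        targets = []
        used_res: set[int] = set()
        for _ in range(n_targets):
            pres = int(rng.integers(1, partner_len + 1))
            if pres in used_res:
                continue
            used_res.add(pres)
            if rng.random() < 0.3 and dna_len:
                tchain = rng.choice(["I", "J"])
                tres = int(rng.integers(1, dna_len + 1))
            else:
                tchain = rng.choice(hist_ids)
                tres = int(rng.integers(1, hist_len + 1))
            if target_use.get((str(tchain), tres), 0) >= 2:
                continue  # at most two movers per target residue
            target_use[(str(tchain), tres)] = \
                target_use.get((str(tchain), tres), 0) + 1
            if rng.random() < 0.6:
                d = float(rng.uniform(4.5, 4.9))
            else:
                d = float(rng.uniform(5.1, 7.0))
            targets.append((str(tchain), tres, pres, round(d, 3)))
        spec.partners.append(PartnerSpec(f"Regulatory protein RP{k+1}",
                                         partner_len, targets))
    return spec


# ---------------------------------------------------------------------------
# mutation tables

@dataclass
class SyntheticMutationSpec:
    seed: int = 0
    # mutations recurring in exactly k distinct clean samples
    recurrence_classes: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 5, 3: 4, 4: 2, 5: 1}
    )
    n_targeted: int = 3
    n_unmatched: int = 1
    n_nonsense: int = 1
    n_dbsnp: int = 2          # recurrent but dbSNP-flagged mutations
    n_high_tmb: int = 2       # recurrent mutations confined to TMB>cutoff samples
    interface_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    interface_fraction: float = 0.5
    recurrence_min: int = 3
    tmb_cutoff: float = 10.0
    genes: tuple = ("H3C1", "H4C1", "H2AC11", "H2BC4")
    cancer_types: tuple = ("Breast Cancer", "Bladder Cancer", "NSCLC", "Glioma")


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def generate_mutation_table(
    spec: SyntheticMutationSpec,
    out_dir: str | Path,
) -> tuple[Path, Path, dict]:
    """Write a MAF-like mutation TSV plus a truth sidecar.

    The truth states the expected combined-set size, refined-set size,
    surviving recurrence classes and per-interaction-class interface
    mapping counts of the refined set, all derivable from the planted
    composition by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    used_keys: set[tuple] = set()
    iface_lookup: dict[tuple[str, int], set[str]] = {}
    for cls, positions in spec.interface_positions.items():
        for gene, pos in positions:
            iface_lookup.setdefault((gene, pos), set()).add(cls)
    sample_counter = [0]

    def new_sample(high_tmb: bool) -> tuple[str, float]:
        sample_counter[0] += 1
        tmb = float(rng.uniform(12, 50)) if high_tmb else float(rng.uniform(0.5, 8))
        return f"s{sample_counter[0]:05d}", round(tmb, 2)

    def new_mutation(on_interface: tuple[str, int] | None = None) -> tuple:
        for _ in range(10000):
            if on_interface is not None:
                gene, pos = on_interface
            else:
                gene = str(rng.choice(spec.genes))
                pos = int(rng.integers(1, 130))
                if (gene, pos) in iface_lookup:
                    continue
            wt, mut = rng.choice(list(_AA20), size=2, replace=False)
            key = (gene, str(wt), pos, str(mut))
            if key not in used_keys:
                used_keys.add(key)
                return key
        raise InfeasibleSpecError("could not draw a fresh mutation key")

    def emit(key, k_samples, *, high_tmb=False, in_dbsnp=False,
             variant_class="missense", sequencing_type="wxs",
             somatic_status="matched"):
        gene, wt, pos, mut = key
        for _ in range(k_samples):
            sid, tmb = new_sample(high_tmb)
            rows.append(
                {
                    "gene": gene,
                    "protein_change": f"{wt}{pos}{mut}",
                    "sample_id": sid,
                    "cancer_type": str(rng.choice(spec.cancer_types)),
                    "variant_class": variant_class,
                    "sequencing_type": sequencing_type,
                    "somatic_status": somatic_status,
                    "sample_tmb": tmb,
                    "in_dbsnp": in_dbsnp,
                }
            )

    # clean mutations by recurrence class; a fraction of the recurrent ones
    # sit on planted interface positions
    recurrent_total = sum(
        c for k, c in spec.recurrence_classes.items() if k >= spec.recurrence_min
    )
    iface_pool = [pos for positions in spec.interface_positions.values()
                  for pos in positions]
    # deduplicate while preserving order
    iface_pool = list(dict.fromkeys(iface_pool))
    n_iface = min(len(iface_pool),
                  int(round(spec.interface_fraction * recurrent_total)))
    iface_assignments = iface_pool[:n_iface]
    mapped_counts: dict[str, int] = {c: 0 for c in spec.interface_positions}
    refined_keys: list[tuple] = []
    assigned = 0
    for k in sorted(spec.recurrence_classes):
        for _ in range(spec.recurrence_classes[k]):
            placement = None
            if k >= spec.recurrence_min and assigned < len(iface_assignments):
                placement = iface_assignments[assigned]
                assigned += 1
            key = new_mutation(placement)
            emit(key, k)
            if k >= spec.recurrence_min:
                refined_keys.append(key)
                if placement is not None:
                    for cls in iface_lookup[placement]:
                        mapped_counts[cls] += 1

    for _ in range(spec.n_targeted):
        emit(new_mutation(), 1, sequencing_type="targeted")
    for _ in range(spec.n_unmatched):
        emit(new_mutation(), 1, somatic_status="unmatched")
    for _ in range(spec.n_nonsense):
        emit(new_mutation(), 1, variant_class="nonsense")
    for _ in range(spec.n_dbsnp):
        emit(new_mutation(), spec.recurrence_min, in_dbsnp=True)
    for _ in range(spec.n_high_tmb):
        emit(new_mutation(), spec.recurrence_min, high_tmb=True)

    import pandas as pd

    df = pd.DataFrame(rows)
    tsv_path = out_dir / f"mutations_seed{spec.seed}.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    refined_size = sum(
        k * c for k, c in spec.recurrence_classes.items()
        if k >= spec.recurrence_min
    )
    truth = {
        "n_raw": len(df),
        "combined_size": len(df) - spec.n_targeted - spec.n_unmatched
        - spec.n_nonsense,
        "refined_size": refined_size,
        "n_unique_refined": recurrent_total,
        "recurrence_classes_surviving": {
            str(k): c for k, c in spec.recurrence_classes.items()
            if k >= spec.recurrence_min
        },
        "mapped_counts": mapped_counts,
        "refined_keys": [list(k) for k in refined_keys],
        "seed": spec.seed,
    }
    truth_path = out_dir / f"mutations_seed{spec.seed}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return tsv_path, truth_path, truth


# ---------------------------------------------------------------------------
# protein-level edge lists with controlled overlap

def generate_edge_lists(
    n_partners: int,
    overlap: float,
    seed: int,
    out_dir: str | Path,
) -> tuple[dict[str, Path], dict]:
    """Structural / crosslink / high-throughput protein-level edge TSVs.

    Each source has ``n_partners`` partner nodes; every pair of sources
    shares ``round(overlap * n_partners)`` of them (a shared core), so
    pairwise overlaps match the request within one node.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    histones = ["H2A", "H2B", "H3", "H4", "H1"]
    n_core = int(round(overlap * n_partners))
    core = [f"COREP{i:04d}" for i in range(n_core)]
    sources = ("structural", "crosslink", "highthroughput")
    paths: dict[str, Path] = {}
    truth_nodes: dict[str, list[str]] = {}
    for src in sources:
        uniq = [f"{src[:2].upper()}P{i:04d}" for i in range(n_partners - n_core)]
        partners = core + uniq
        edges = []
        for p in partners:
            for h in rng.choice(histones, size=int(rng.integers(1, 3)),
                                replace=False):
                edges.append((str(h), p))
        path = out_dir / f"{src}_edges_seed{seed}.tsv"
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        paths[src] = path
        truth_nodes[src] = partners
    truth = {
        "n_partners": n_partners,
        "overlap": overlap,
        "n_core": n_core,
        "partners": truth_nodes,
        "pairwise_overlap": {
            f"{a}|{b}": len(set(truth_nodes[a]) & set(truth_nodes[b]))
            for i, a in enumerate(sources) for b in sources[i + 1:]
        },
        "seed": seed,
    }
    truth_path = out_dir / f"edge_lists_seed{seed}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths, truth


def generate_scalefree_graph(
    n: int,
    m: int,
    seed: int,
    out_path: str | Path | None = None,
) -> nx.Graph:
    """Preferential-attachment graph: n nodes, exactly m(n−m) edges.

    Barabási–Albert-style growth from m seed nodes, with the first m added
    nodes wired to every seed so that the minimum degree is m everywhere
    (plain BA growth can leave a seed node under-attached).
    """
    if not n > m >= 1:
        raise ValueError("need n > m >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    repeated: list[int] = []
    for new in range(m, n):
        if new < 2 * m:
            targets = list(range(m))
        else:
            chosen: set[int] = set()
            while len(chosen) < m:
                chosen.add(repeated[int(rng.integers(len(repeated)))])
            targets = sorted(chosen)
        for t in targets:
            graph.add_edge(new, t)
            repeated.extend((new, t))
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\t{b}\n")
    return graph
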