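"""Structure parsing, chain typing and histone annotation.

Coordinates are read with gemmi (PDB and mmCIF); the module keeps a light
in-memory representation — chains of residues of atoms — sufficient for
heavy-atom contact analysis.  Only the first model is used and only
alternate location 'A' (or blank) is kept.  Waters and non-polymer ligands
are excluded from polymer chains but retained in a separate ligand list so
nothing is silently discarded.

Chain typing follows component composition: a chain whose polymer residues
are deoxynucleotides is DNA, ribonucleotides RNA, amino acids protein;
hybrid chains are classified by majority composition with a warning.
Modified amino acids (ALY, M3L, ...) are polymer residues, not ligands, so
PTM-site contacts remain detectable downstream.
"""

from __future__ import annotations

import copy as _copy
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from histonet import config as _config
from histonet.exceptions import (
    ConfigurationError,
    EmptyStructureError,
    MappingConflictError,
    StructureParseError,
    UnknownChainError,
)

logger = logging.getLogger(__name__)

_HYDROGEN_ELEMENTS = {"H", "D"}
# Deoxynucleotide components beyond gemmi's tables are rare; gemmi covers
# DA/DC/DG/DT/DU/DI and most modified variants.


@dataclass
class AtomRecord:
    """One atom of a polymer residue."""

    chain_id: str
    residue_seq_id: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) in Å
    is_heavy: bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureParseError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_seq_id}"
            )


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    sequence_position: int | None = None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ChainRecord:
    chain_id: str
    molecule_class: str  # protein | dna | rna | other
    residues: list[Residue] = field(default_factory=list)
    entity_name: str = ""
    uniprot_id: str | None = None

    def residue(self, seq_id: int) -> Residue | None:
        for res in self.residues:
            if res.seq_id == seq_id:
                return res
        return None

    def one_letter_sequence(self) -> str:
        out = []
        for res in self.residues:
            info = gemmi.find_tabulated_residue(res.name)
            code = info.one_letter_code.upper() if info else "X"
            out.append(code if code.strip() else "X")
        return "".join(out)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class HistoneAnnotation:
    """Role of one chain in the complex: histone (with type), partner or dna."""

    chain_id: str
    role: str  # histone | partner | dna
    histone_type: str | None = None  # H1 | H2A | H2B | H3 | H4
    variant_label: str | None = None


@dataclass
class Structure:
    structure_id: str
    chains: list[ChainRecord] = field(default_factory=list)
    ligands: list[tuple[str, str, int]] = field(default_factory=list)
    # ligands: (chain_id, residue_name, residue_seq_id) of waters/non-polymer

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise UnknownChainError(f"no chain {chain_id!r} in {self.structure_id}")

    def chain_ids(self) -> list[str]:
        return [ch.chain_id for ch in self.chains]

    @property
    def n_atoms(self) -> int:
        return sum(ch.n_atoms for ch in self.chains)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parsing

def _residue_category(name: str, ptm_components: set[str]) -> str:
    """aa | dna | rna | water | other for one chemical component id."""
    name = name.upper()
    if name in ptm_components:
        return "aa"
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return "other"
    if info.is_water():
        return "water"
    if info.is_amino_acid():
        return "aa"
    if info.is_nucleic_acid():
        return "dna" if info.kind == gemmi.ResidueKind.DNA else "rna"
    return "other"


def _keep_altloc(altloc: str) -> bool:
    return altloc in ("", " ", "\x00", "A")


def _parse_entity_names_pdb(text: str) -> dict[str, str]:
    """chain id -> COMPND MOLECULE name from PDB header records."""
    parts = []
    for line in text.splitlines():
        if line.startswith("COMPND"):
            parts.append(line[10:].strip())
    compnd = " ".join(parts)
    names: dict[str, str] = {}
    for segment in re.split(r"MOL_ID:", compnd)[1:]:
        mol = re.search(r"MOLECULE:\s*([^;]+);", segment)
        chains = re.search(r"CHAIN:\s*([^;]+);?", segment)
        if mol and chains:
            molname = mol.group(1).strip()
            for cid in chains.group(1).split(","):
                names[cid.strip()] = molname
    return names


def _parse_entity_names_mmcif(path: str | Path) -> dict[str, str]:
    """chain id -> _entity.pdbx_description from an mmCIF file."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception:  # header extraction is best-effort
        return {}
    desc: dict[str, str] = {}
    for row in block.find("_entity.", ["id", "pdbx_description"]):
        desc[row[0]] = gemmi.cif.as_string(row[1])
    names: dict[str, str] = {}
    for row in block.find("_entity_poly.", ["entity_id", "pdbx_strand_id"]):
        name = desc.get(row[0], "")
        for cid in gemmi.cif.as_string(row[1]).split(","):
            names[cid.strip()] = name
    if not names:
        # fall back to struct_asym mapping
        for row in block.find("_struct_asym.", ["id", "entity_id"]):
            names[row[0]] = desc.get(row[1], "")
    return names


def parse_structure(
    path: str | Path,
    format: str = "auto",
    ptm_map: dict[str, str] | None = None,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Structure file.
    format:
        ``pdb``, ``mmcif`` or ``auto`` (detect from contents/extension).
    ptm_map:
        Chemical-component -> PTM-type map; listed components are treated
        as polymer amino acids.  Defaults to the bundled map.

    Raises
    ------
    StructureParseError
        Unreadable or syntactically invalid file.
    EmptyStructureError
        File contains no polymer chains (e.g. waters only).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} has no models")

    ptm_components = set((ptm_map or _config.load_ptm_map()).keys())

    is_cif = st.input_format == gemmi.CoorFormat.Mmcif or (
        fmt == gemmi.CoorFormat.Mmcif
    )
    if is_cif:
        entity_names = _parse_entity_names_mmcif(path)
    else:
        entity_names = _parse_entity_names_pdb(path.read_text())

    structure = Structure(structure_id=st.name or path.stem)
    model = st[0]  # first model only
    for gchain in model:
        residues: list[Residue] = []
        counts = {"aa": 0, "dna": 0, "rna": 0}
        for gres in gchain:
            cat = _residue_category(gres.name, ptm_components)
            if cat in ("water", "other"):
                structure.ligands.append((gchain.name, gres.name, gres.seqid.num))
                continue
            counts[cat] += 1
            res = Residue(seq_id=gres.seqid.num, name=gres.name.upper())
            for gatom in gres:
                if not _keep_altloc(gatom.altloc):
                    continue
                element = gatom.element.name.upper()
                res.atoms.append(
                    AtomRecord(
                        chain_id=gchain.name,
                        residue_seq_id=gres.seqid.num,
                        residue_name=gres.name.upper(),
                        atom_name=gatom.name,
                        element=element,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        is_heavy=element not in _HYDROGEN_ELEMENTS,
                    )
                )
            if res.atoms:
                residues.append(res)
        if not residues:
            continue
        total = sum(counts.values())
        majority = max(counts, key=lambda k: counts[k])
        if counts[majority] < total:
            logger.warning(
                "chain %s is a hybrid (%s); majority composition '%s' wins",
                gchain.name, counts, majority,
            )
        molecule_class = {"aa": "protein", "dna": "dna", "rna": "rna"}[majority]
        structure.chains.append(
            ChainRecord(
                chain_id=gchain.name,
                molecule_class=molecule_class,
                residues=residues,
                entity_name=entity_names.get(gchain.name, ""),
            )
        )
    if not structure.chains:
        raise EmptyStructureError(f"{path} contains no polymer chains")
    return structure


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Serialize a Structure back to PDB or mmCIF via gemmi.

    Chain ids, residue ids and coordinates survive a round trip (PDB
    coordinates at 3 decimals); header entity names are not regenerated.
    """
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.atom_name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# chain classification

def _global_identity(seq: str, ref: str) -> float:
    """Global sequence identity: matched positions / longer length."""
    if not seq or not ref:
        return 0.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    try:
        aln = aligner.align(seq, ref)[0]
    except (ValueError, IndexError):
        return 0.0
    matches = 0
    for (s_blk, r_blk) in zip(aln.aligned[0], aln.aligned[1]):
        a = seq[s_blk[0]:s_blk[1]]
        b = ref[r_blk[0]:r_blk[1]]
        matches += sum(x == y for x, y in zip(a, b))
    return matches / max(len(seq), len(ref))


def classify_chains(
    structure: Structure,
    histone_config: dict | None = None,
) -> list[HistoneAnnotation]:
    """Annotate every polymer chain as histone (typed), partner or dna.

    Protein chains are matched against per-type keywords on the entity name
    first; chains without a keyword hit fall back to global sequence
    identity against a bundled reference sequence per histone type
    (threshold ``identity_threshold``, default 0.6).  Nucleic chains get
    role ``dna``.
    """
    cfg = histone_config if histone_config is not None else _config.load_histone_config()
    if not cfg or not cfg.get("types"):
        raise ConfigurationError("empty histone configuration")
    threshold = cfg.get("identity_threshold", _config.DEFAULTS["identity_threshold"])

    annotations: list[HistoneAnnotation] = []
    for chain in structure.chains:
        if chain.molecule_class in ("dna", "rna"):
            annotations.append(HistoneAnnotation(chain.chain_id, "dna"))
            continue
        name = (chain.entity_name or "").lower()
        htype_found = None
        for htype, entry in cfg["types"].items():
            if any(kw.lower() in name for kw in entry["keywords"] if kw):
                htype_found = htype
                break
        if htype_found is None and chain.residues:
            seq = chain.one_letter_sequence()
            if len(seq) >= 10:
                best, best_id = None, 0.0
                for htype, entry in cfg["types"].items():
                    ref = entry.get("reference", "")
                    if not ref:
                        continue
                    ident = _global_identity(seq, ref)
                    if ident > best_id:
                        best, best_id = htype, ident
                if best is not None and best_id >= threshold:
                    htype_found = best
        if htype_found is not None:
            annotations.append(
                HistoneAnnotation(
                    chain.chain_id, "histone", htype_found,
                    variant_label=chain.entity_name or None,
                )
            )
        else:
            annotations.append(
                HistoneAnnotation(
                    chain.chain_id, "partner",
                    variant_label=chain.entity_name or None,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# residue-number mapping

def read_mapping_table(path: str | Path) -> pd.DataFrame:
    """Read a SIFTS-like TSV: chain_id, struct_resid, seq_pos, uniprot_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "uniprot_id": str})
    required = {"chain_id", "struct_resid", "seq_pos"}
    missing = required - set(df.columns)
    if missing:
        raise MappingConflictError(f"mapping table missing columns: {sorted(missing)}")
    return df


def apply_residue_mapping(
    structure: Structure,
    mapping: str | Path | pd.DataFrame = "identity",
) -> Structure:
    """Attach UniProt-like sequence positions to residues.

    ``mapping`` is either the string ``"identity"`` (sequence_position =
    structure residue number), a DataFrame, or a path to a TSV with columns
    chain_id, struct_resid, seq_pos, uniprot_id.  Residues without a mapping
    row keep ``sequence_position=None`` and are excluded from
    sequence-coordinate outputs downstream.
    """
    out = structure.copy()
    if isinstance(mapping, str) and mapping == "identity":
        for chain in out.chains:
            for res in chain.residues:
                res.sequence_position = res.seq_id
        return out
    if not isinstance(mapping, pd.DataFrame):
        mapping = read_mapping_table(mapping)
    dup = mapping.duplicated(subset=["chain_id", "struct_resid"], keep=False)
    if dup.any():
        rows = mapping.loc[dup, ["chain_id", "struct_resid"]].drop_duplicates()
        pairs = [tuple(r) for r in rows.itertuples(index=False)]
        raise MappingConflictError(f"duplicate mapping rows for {pairs}")
    known = set(out.chain_ids())
    lut: dict[tuple[str, int], tuple[int, str | None]] = {}
    for row in mapping.itertuples(index=False):
        cid = str(row.chain_id)
        if cid not in known:
            logger.warning("mapping row references unknown chain %r; skipped", cid)
            continue
        uid = getattr(row, "uniprot_id", None)
        lut[(cid, int(row.struct_resid))] = (int(row.seq_pos), uid)
    for chain in out.chains:
        uniprot_seen = set()
        for res in chain.residues:
            hit = lut.get((chain.chain_id, res.seq_id))
            if hit is not None:
                res.sequence_position = hit[0]
                if hit[1]:
                    uniprot_seen.add(hit[1])
            else:
                res.sequence_position = None
        if len(uniprot_seen) == 1:
            chain.uniprot_id = next(iter(uniprot_seen))
    return out


def prune_chains(structure: Structure, keep: set[str]) -> Structure:
    """Return a new structure containing exactly the kept chains.

    Used e.g. to strip partner chains from a nucleosome complex before
    histone–histone / histone–DNA binding-energy prediction.
    """
    keep = set(keep)
    unknown = keep - set(structure.chain_ids())
    if unknown:
        raise UnknownChainError(f"unknown chain ids: {sorted(unknown)}")
    if not keep:
        raise EmptyStructureError("prune_chains: empty keep set")
    out = structure.copy()
    out.chains = [ch for ch in out.chains if ch.chain_id in keep]
    out.ligands = [lg for lg in out.ligands if lg[0] in keep]
    return out
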