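"""Shared fixtures: toy complexes with planted contacts, oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from histonet import structure_io, synthetic
from histonet.interfaces import extract_interfaces


def all_pairs_contact_oracle(structure, cutoff=5.0):
    """Independent brute-force contact oracle: the full O(n^2) heavy-atom
    distance matrix, no spatial indexing.

    Returns {(chain,res),(chain,res) sorted: (min_dist, n_pairs)}.
    """
    chains, residues, positions = [], [], []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    chains.append(chain.chain_id)
                    residues.append(res.seq_id)
                    positions.append(atom.position)
    pos = np.asarray(positions)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    out = {}
    ii, jj = np.where(dist <= cutoff)
    for i, j in zip(ii, jj):
        if i >= j or chains[i] == chains[j]:
            continue
        key = tuple(sorted(((chains[i], residues[i]), (chains[j], residues[j]))))
        d = float(dist[i, j])
        cur = out.get(key)
        out[key] = (d, 1) if cur is None else (min(cur[0], d), cur[1] + 1)
    return out


def contacts_as_dict(contacts):
    return {
        tuple(sorted(((c.chain_a, c.residue_a), (c.chain_b, c.residue_b)))):
        (c.min_distance, c.atom_contact_count)
        for c in contacts
    }


def standard_toy_spec(seed=1, structure_id="TOY1"):
    """Toy nucleosome complex planting all four interaction classes."""
    spec = synthetic.ToyComplexSpec(structure_id=structure_id, seed=seed)
    spec.partners.append(
        synthetic.PartnerSpec(
            "Regulatory protein RP1", 12,
            [("A", 5, 1, 4.6), ("I", 3, 2, 4.8), ("B", 7, 3, 5.5)],
        )
    )
    spec.extra_pairs.append(synthetic.PlantedPair("A", 10, "B", 10, 4.7))
    spec.extra_pairs.append(synthetic.PlantedPair("I", 10, "C", 12, 4.5))
    return spec


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """Parsed toy complex + annotations + extraction + planted truth."""
    out = tmp_path_factory.mktemp("toy")
    spec = standard_toy_spec()
    pdb_path, truth_path, truth = synthetic.generate_toy_complex(spec, out)
    st = structure_io.parse_structure(pdb_path)
    st = structure_io.apply_residue_mapping(st, "identity")
    annotations = {a.chain_id: a for a in structure_io.classify_chains(st)}
    extraction = extract_interfaces(st, annotations)
    return {
        "spec": spec,
        "pdb_path": pdb_path,
        "truth": truth,
        "structure": st,
        "annotations": annotations,
        "extraction": extraction,
    }


def poly_ala_alignment(rows):
    """Aligned FASTA stand-in: rows = [(id, aligned_sequence_string)]."""
    return MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in rows]
    )


def alignments_for(structure, annotations):
    """Per-histone-type single-row alignments matching the structure's
    histone protein ids (ungapped poly-A rows of each chain's length)."""
    from histonet.interfaces import protein_node_id

    rows: dict[str, list] = {}
    seen = set()
    for chain in structure.chains:
        ann = annotations[chain.chain_id]
        if ann.role != "histone":
            continue
        pid = protein_node_id(chain, ann)
        if pid in seen:
            continue
        seen.add(pid)
        rows.setdefault(ann.histone_type, []).append(
            (pid, "A" * len(chain.residues))
        )
    return {
        htype: poly_ala_alignment(entries) for htype, entries in rows.items()
    }


@pytest.fixture(scope="session")
def toy_alignments(toy_bundle):
    return alignments_for(toy_bundle["structure"], toy_bundle["annotations"])
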