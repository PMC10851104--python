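"""Cancer-associated histone mutation curation, interface mapping and
disruption calling.

The curation mirrors a cBioPortal-style workflow.  The *combined* set
keeps somatic missense calls after dropping targeted-panel sequencing and
somatic-unmatched samples (optionally unioned with an external dataset,
deduplicated on gene/protein-change/sample).  The *refined* set further
drops records from hypermutated samples (tumor mutation burden strictly
greater than 10 mutations/Mb), known dbSNP variants, and mutations seen in
fewer than three distinct samples after the preceding filters.

Mapped onto the residue-level interaction network, a mutation belongs to an
interaction class (HHI/HDI/HPI) iff its (gene product, sequence position)
node participates in at least one edge of that class; one mutation can sit
on several interfaces.

Binding-energy disruption uses a pluggable ddG predictor contract
``predictor(structure, chain_id, position, wt, mut, mode) -> kcal/mol``
with positive values destabilizing.  For HHI/HDI predictions the partner
chains are pruned from the complex first; HPI predictions see the full
complex.  A deterministic physicochemical surrogate predictor ships for
testing and is explicitly non-physical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from histonet.exceptions import (
    DegenerateGroupsError,
    HistonetError,
    MissingColumnError,
    TmbUnderivableError,
)
from histonet.structure_io import Structure, prune_chains

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "gene", "protein_change", "sample_id", "cancer_type", "variant_class",
    "sequencing_type", "somatic_status",
]
OPTIONAL_COLUMNS = ["sample_tmb", "in_dbsnp"]
MUTATION_KEY = ["gene", "wt_aa", "position", "mut_aa"]

_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")

#: Five-way physicochemical partition of the 20 standard amino acids.
PHYSCHEM: dict[str, str] = {
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "polar_uncharged" for aa in "STNQC"},
    **{aa: "nonpolar_aliphatic" for aa in "GAVLIMP"},
    **{aa: "nonpolar_aromatic" for aa in "FWY"},
}

_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
_CHARGE = {**{aa: 1 for aa in "KR"}, "H": 0.5, **{aa: -1 for aa in "DE"}}


# ---------------------------------------------------------------------------
# parsing and set construction

def parse_mutations(source) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a mutation TSV (or DataFrame) into records plus a reject report.

    Protein-change strings of the form ``R29P`` are decomposed into
    wt_aa/position/mut_aa columns; malformed rows land in the reject report
    with a reason instead of being silently dropped.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype={"gene": str, "sample_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"mutation table missing columns: {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["in_dbsnp"] = df["in_dbsnp"].fillna(False).astype(bool)

    parsed = df["protein_change"].astype(str).str.extract(_CHANGE_RE)
    parsed.columns = ["wt_aa", "position", "mut_aa"]
    bad = parsed["wt_aa"].isna()
    same = (~bad) & (parsed["wt_aa"] == parsed["mut_aa"])
    rejects = df[bad | same].copy()
    rejects["reject_reason"] = np.where(
        bad[bad | same], "unparseable protein change", "silent change"
    )
    good = df[~(bad | same)].copy()
    good[["wt_aa", "mut_aa"]] = parsed.loc[good.index, ["wt_aa", "mut_aa"]]
    good["position"] = parsed.loc[good.index, "position"].astype(int)
    if (good["position"] < 1).any():
        raise HistonetError("protein positions must be >= 1")
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


@dataclass
class MutationSet:
    label: str                # combined | refined
    records: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.records)

    def recurrence(self) -> pd.Series:
        """Distinct-sample count per (gene, wt_aa, position, mut_aa)."""
        if self.records.empty:
            return pd.Series(dtype=int)
        return self.records.groupby(MUTATION_KEY)["sample_id"].nunique()


def _combined_filters(df: pd.DataFrame) -> pd.DataFrame:
    return df[
        (df["sequencing_type"].str.lower() != "targeted")
        & (df["somatic_status"].str.lower() != "unmatched")
        & (df["variant_class"].str.lower() == "missense")
    ]


def build_combined_set(
    records: pd.DataFrame,
    external: pd.DataFrame | None = None,
) -> MutationSet:
    """Combined mutation set: drop targeted sequencing and somatic-unmatched
    records, keep missense, union with an optional external dataset
    deduplicated on (gene, protein_change, sample)."""
    parts = [_combined_filters(records)]
    if external is not None and len(external):
        parts.append(_combined_filters(external))
    merged = pd.concat(parts, ignore_index=True)
    merged = merged.drop_duplicates(
        subset=["gene", "protein_change", "sample_id"], keep="first"
    ).reset_index(drop=True)
    return MutationSet("combined", merged)


def derive_tmb(
    records: pd.DataFrame,
    callable_mb: float = 38.0,
) -> pd.Series:
    """Per-sample TMB: input column when present, else mutation count / Mb."""
    provided = records.groupby("sample_id")["sample_tmb"].first()
    counts = records.groupby("sample_id").size() / callable_mb
    return provided.fillna(counts)


def build_refined_set(
    combined: MutationSet,
    tmb_cutoff: float = 10.0,
    recurrence_min: int = 3,
    callable_mb: float | None = 38.0,
) -> MutationSet:
    """Refined set: drop hypermutator samples (TMB strictly > cutoff), drop
    dbSNP variants, keep mutations recurring in >= recurrence_min distinct
    samples after the preceding filters."""
    df = combined.records
    if df.empty:
        return MutationSet("refined", df.copy())
    if callable_mb is None:
        missing = df.loc[df["sample_tmb"].isna(), "sample_id"].unique()
        if len(missing):
            raise TmbUnderivableError(
                f"TMB missing and derivation disabled for samples: "
                f"{sorted(missing)}"
            )
        tmb = df.groupby("sample_id")["sample_tmb"].first()
    else:
        tmb = derive_tmb(df, callable_mb)
    keep_samples = tmb[tmb <= tmb_cutoff].index
    df = df[df["sample_id"].isin(keep_samples)]
    df = df[~df["in_dbsnp"]]
    recur = df.groupby(MUTATION_KEY)["sample_id"].nunique()
    recurrent_keys = set(recur[recur >= recurrence_min].index)
    mask = df.set_index(MUTATION_KEY).index.isin(recurrent_keys)
    return MutationSet("refined", df[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# interface mapping

def map_mutations_to_interfaces(
    mset: MutationSet,
    residue_network,
    gene_to_protein: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Map unique mutations onto residue-level interface classes.

    A mutation maps to class X iff its ``<protein>/<position>`` node has at
    least one edge of class X in the residue network.  Returns per-class
    tables plus ``multi`` (>=2 classes), ``triple`` (all of HHI/HDI/HPI)
    and ``unmapped``.
    """
    gene_to_protein = gene_to_protein or {}
    graph = residue_network.graph if hasattr(residue_network, "graph") else residue_network
    if mset.records.empty:
        empty = mset.records.copy()
        return {c: empty.copy() for c in ("HHI", "HDI", "HPI", "multi", "triple", "unmapped")}
    recur = mset.recurrence()
    uniq = mset.records.drop_duplicates(subset=MUTATION_KEY).copy()
    uniq["recurrence"] = [
        int(recur[tuple(row)]) for row in uniq[MUTATION_KEY].itertuples(index=False)
    ]
    class_rows: dict[str, list] = {c: [] for c in ("HHI", "HDI", "HPI")}
    multi_rows, triple_rows, unmapped_rows = [], [], []
    for _, row in uniq.iterrows():
        protein = gene_to_protein.get(row["gene"], row["gene"])
        node = f"{protein}/{row['position']}"
        classes = set()
        if node in graph:
            for _, _, d in graph.edges(node, data=True):
                cls = d.get("interaction_class")
                if cls in ("HHI", "HDI", "HPI"):
                    classes.add(cls)
        if not classes:
            unmapped_rows.append(row)
            continue
        for cls in classes:
            class_rows[cls].append(row)
        if len(classes) >= 2:
            multi_rows.append(row)
        if classes == {"HHI", "HDI", "HPI"}:
            triple_rows.append(row)

    def frame(rows):
        return pd.DataFrame(rows).reset_index(drop=True) if rows else uniq.iloc[0:0].copy()

    out = {c: frame(r) for c, r in class_rows.items()}
    out["multi"] = frame(multi_rows)
    out["triple"] = frame(triple_rows)
    out["unmapped"] = frame(unmapped_rows)
    return out


# ---------------------------------------------------------------------------
# physicochemical profiling

def classify_physchem(aa: str) -> str:
    """One of positive / negative / polar_uncharged / nonpolar_aliphatic /
    nonpolar_aromatic for a standard amino acid."""
    try:
        return PHYSCHEM[aa.upper()]
    except KeyError:
        raise HistonetError(f"nonstandard amino acid {aa!r}") from None


def profile_interface_change(mapped: pd.DataFrame) -> pd.DataFrame:
    """Category counts of wild-type vs mutant residues of mapped mutations."""
    categories = sorted(set(PHYSCHEM.values()))
    wt = mapped["wt_aa"].map(classify_physchem).value_counts()
    mut = mapped["mut_aa"].map(classify_physchem).value_counts()
    return pd.DataFrame(
        {
            "category": categories,
            "wild_type": [int(wt.get(c, 0)) for c in categories],
            "mutant": [int(mut.get(c, 0)) for c in categories],
        }
    )


# ---------------------------------------------------------------------------
# ddG prediction

@dataclass(frozen=True)
class DdgRecord:
    gene: str
    wt_aa: str
    position: int
    mut_aa: str
    interaction_class: str
    ddg: float                 # kcal/mol, positive = destabilizing
    predictor_id: str
    structure_id: str


def surrogate_predictor(structure, chain_id, position, wt, mut, mode) -> float:
    """Deterministic physicochemical ddG surrogate — NOT a physical model.

    Scores hydropathy and charge change, with a fixed mode-dependent
    offset; useful only as a reproducible stand-in where a trained
    predictor (protein–protein or protein–DNA) would be plugged in.
    """
    dh = abs(_KYTE_DOOLITTLE[wt] - _KYTE_DOOLITTLE[mut])
    dq = abs(_CHARGE.get(wt, 0) - _CHARGE.get(mut, 0))
    base = 0.25 * dh + 0.9 * dq
    if mode == "protein-DNA" and _CHARGE.get(wt, 0) > _CHARGE.get(mut, 0):
        base += 0.5  # losing positive charge near DNA scored as destabilizing
    return round(base, 4)


surrogate_predictor.predictor_id = "surrogate-physchem-v1"


def _find_mutation_chain(structure: Structure, annotations, gene, position,
                         gene_to_protein) -> str | None:
    from histonet.interfaces import protein_node_id

    ann = annotations if isinstance(annotations, dict) else {
        a.chain_id: a for a in annotations
    }
    protein = gene_to_protein.get(gene, gene)
    for chain in structure.chains:
        a = ann[chain.chain_id]
        if a.role != "histone":
            continue
        if protein_node_id(chain, a) != protein:
            continue
        for res in chain.residues:
            if res.sequence_position == position:
                return chain.chain_id
    return None


def predict_ddg(
    mutation: dict | pd.Series,
    structure: Structure,
    annotations,
    interaction_class: str,
    predictor=surrogate_predictor,
    gene_to_protein: dict[str, str] | None = None,
) -> DdgRecord | None:
    """Predict the binding free-energy change of one histone mutation.

    For HHI/HDI the partner chains are removed from the complex before the
    predictor is called (histone+DNA only); for HPI the full complex is
    used.  Returns None (with a log record) when the mutated position is
    absent from the structure or the predictor fails.
    """
    ann = annotations if isinstance(annotations, dict) else {
        a.chain_id: a for a in annotations
    }
    gene_to_protein = gene_to_protein or {}
    gene, wt, pos, mut = (
        mutation["gene"], mutation["wt_aa"], int(mutation["position"]),
        mutation["mut_aa"],
    )
    chain_id = _find_mutation_chain(structure, ann, gene, pos, gene_to_protein)
    if chain_id is None:
        logger.info(
            "skip %s %s%d%s: position absent from %s",
            gene, wt, pos, mut, structure.structure_id,
        )
        return None
    if interaction_class in ("HHI", "HDI"):
        keep = {
            cid for cid, a in ann.items() if a.role in ("histone", "dna")
        } & set(structure.chain_ids())
        target = prune_chains(structure, keep)
    elif interaction_class == "HPI":
        target = structure
    else:
        raise ValueError(f"no ddG contract for class {interaction_class!r}")
    mode = "protein-DNA" if interaction_class == "HDI" else "protein-protein"
    try:
        ddg = float(predictor(target, chain_id, pos, wt, mut, mode))
    except Exception as exc:  # predictor failure recorded, not fatal
        logger.warning("predictor failed for %s%d%s: %s", wt, pos, mut, exc)
        return None
    return DdgRecord(
        gene=gene, wt_aa=wt, position=pos, mut_aa=mut,
        interaction_class=interaction_class, ddg=ddg,
        predictor_id=getattr(predictor, "predictor_id", predictor.__name__),
        structure_id=structure.structure_id,
    )


def select_disruptive(
    ddg_records: list[DdgRecord],
    recurrence: dict[tuple, int],
    thresholds: dict[str, float] | None = None,
    recurrence_min: int = 3,
) -> pd.DataFrame:
    """Recurrent mutations whose mean ddG passes the per-class threshold.

    Defaults: HDI >= 1.0 kcal/mol; HHI and HPI >= 1.5 kcal/mol.  ddG rows
    duplicated for the same (mutation, class, structure) are deduplicated
    before averaging; output order is canonical (class, gene, position).
    """
    thresholds = thresholds or {"HDI": 1.0, "HHI": 1.5, "HPI": 1.5}
    seen = {}
    for r in ddg_records:
        key = (r.gene, r.wt_aa, r.position, r.mut_aa, r.interaction_class,
               r.structure_id)
        seen.setdefault(key, r)
    grouped: dict[tuple, list[float]] = {}
    for r in seen.values():
        grouped.setdefault(
            (r.gene, r.wt_aa, r.position, r.mut_aa, r.interaction_class), []
        ).append(r.ddg)
    rows = []
    for (gene, wt, pos, mut, cls), values in grouped.items():
        mean_ddg = float(np.mean(values))
        rec = recurrence.get((gene, wt, pos, mut), 0)
        if rec >= recurrence_min and mean_ddg >= thresholds.get(cls, np.inf):
            rows.append(
                {
                    "gene": gene, "wt_aa": wt, "position": pos, "mut_aa": mut,
                    "interaction_class": cls, "mean_ddg": round(mean_ddg, 4),
                    "recurrence": int(rec),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene", "wt_aa", "position", "mut_aa", "interaction_class",
                 "mean_ddg", "recurrence"],
    )
    return out.sort_values(
        ["interaction_class", "gene", "position", "mut_aa"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparison

def compare_ddg_groups(
    groups: dict[str, np.ndarray | list],
    alpha_flags: tuple[float, float] = (0.05, 0.005),
) -> dict:
    """Group medians plus all-pairs Tukey HSD on ddG distributions.

    Flags each pair at the 0.05 and 0.005 levels (the one/two-star
    convention).  Requires >= 2 groups with >= 2 values each.
    """
    clean = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(clean) < 2 or any(len(v) < 2 for v in clean.values()):
        raise DegenerateGroupsError(
            "need >= 2 groups with >= 2 values each for Tukey HSD"
        )
    values = np.concatenate(list(clean.values()))
    labels = np.concatenate(
        [np.full(len(v), k, dtype=object) for k, v in clean.items()]
    )
    res = pairwise_tukeyhsd(values, labels, alpha=alpha_flags[0])
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    table["p_adj"] = res.pvalues
    table[f"sig_{alpha_flags[0]}"] = res.pvalues < alpha_flags[0]
    table[f"sig_{alpha_flags[1]}"] = res.pvalues < alpha_flags[1]
    return {
        "medians": {k: float(np.median(v)) for k, v in clean.items()},
        "pairs": table,
    }
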