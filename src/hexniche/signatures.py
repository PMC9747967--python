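"""Cytokine responder-gene signature derivation.

The cascade: filter the in-vitro stimulation DEG table per cytokine
(strict thresholds: p < 0.05, adjusted p < 0.05, log2FC above a
per-cytokine cut — 1.5 for IL17A and IFNG, 1 for IL13), intersect with
the spatially derived DEG list for that cytokine, purify candidates by
removing any gene shared between signatures, and optionally union a
curated literature gene list (IL13 in practice).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DEFAULT_FC_THRESHOLDS",
    "StimDegTable",
    "ResponderSignature",
    "load_stim_table",
    "filter_stim_deg",
    "intersect_with_spatial",
    "purify_signatures",
    "add_literature_genes",
    "derive_signatures",
]

#: log2 fold-change cuts of the stimulation filter, per cytokine.
DEFAULT_FC_THRESHOLDS = {"IFNG": 1.5, "IL17A": 1.5, "IL13": 1.0}
DEFAULT_P_CUT = 0.05
DEFAULT_PADJ_CUT = 0.05

STIM_COLUMNS = ["gene", "cytokine", "log2FC", "p_value", "adj_p_value"]

StimDegTable = pd.DataFrame  # rows of (gene, cytokine, log2FC, p_value, adj_p_value)


@dataclass
class ResponderSignature:
    cytokine: str
    genes: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)  # gene -> source

    def __post_init__(self) -> None:
        seen = set()
        uniq = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        self.genes = uniq
        for g in self.genes:
            self.provenance.setdefault(g, "in_vitro∩spatial")

    def as_dict(self) -> dict:
        return {
            "cytokine": self.cytokine,
            "genes": list(self.genes),
            "provenance": dict(self.provenance),
        }


def load_stim_table(path) -> StimDegTable:
    df = pd.read_csv(path)
    missing = set(STIM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stimulation table missing columns: {sorted(missing)}")
    if df.duplicated(["gene", "cytokine"]).any():
        raise ValueError("stimulation table must have one row per (gene, cytokine)")
    return df


def filter_stim_deg(
    table: StimDegTable,
    cytokine: str,
    fc_thresholds: dict[str, float] | None = None,
    p_cut: float = DEFAULT_P_CUT,
    padj_cut: float = DEFAULT_PADJ_CUT,
) -> list[str]:
    """Genes passing all three stimulation thresholds for one cytokine.

    Comparisons are strict: ``log2FC > cut``, ``p < p_cut``,
    ``padj < padj_cut``.
    """
    fc_thresholds = fc_thresholds or DEFAULT_FC_THRESHOLDS
    if cytokine not in set(table["cytokine"]):
        raise ValueError(f"cytokine {cytokine!r} absent from stimulation table")
    if cytokine not in fc_thresholds:
        raise ValueError(f"no log2FC threshold configured for {cytokine!r}")
    fc_cut = fc_thresholds[cytokine]
    sub = table[table["cytokine"] == cytokine]
    mask = (
        (sub["log2FC"] > fc_cut)
        & (sub["p_value"] < p_cut)
        & (sub["adj_p_value"] < padj_cut)
    )
    return sorted(sub.loc[mask, "gene"].tolist())


def intersect_with_spatial(
    stim_genes, spatial_genes, cytokine: str | None = None
) -> list[str]:
    """Intersection of stimulation-filtered genes with the spatially
    significant DEG set; an empty intersection is allowed (warned)."""
    out = sorted(set(stim_genes) & set(spatial_genes))
    if not out:
        warnings.warn(
            f"empty signature after spatial intersection"
            + (f" for {cytokine}" if cytokine else "")
        )
    return out


def purify_signatures(signatures: list[ResponderSignature]) -> list[ResponderSignature]:
    """Remove every gene appearing in two or more signatures from all of
    them; the result is pairwise disjoint.  Idempotent and independent of
    signature order."""
    counts: dict[str, int] = {}
    for sig in signatures:
        for g in set(sig.genes):
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= 2}
    out = []
    for sig in signatures:
        kept = [g for g in sig.genes if g not in shared]
        out.append(
            ResponderSignature(
                cytokine=sig.cytokine,
                genes=kept,
                provenance={g: sig.provenance.get(g, "in_vitro∩spatial") for g in kept},
            )
        )
    return out


def add_literature_genes(
    signature: ResponderSignature,
    literature_genes,
    other_signatures: list[ResponderSignature] | None = None,
) -> ResponderSignature:
    """Union a curated literature gene list into a purified signature.

    A literature gene already present in another cytokine's signature
    would break pairwise disjointness and is fatal.
    """
    literature_genes = list(literature_genes)
    if other_signatures:
        for other in other_signatures:
            if other.cytokine == signature.cytokine:
                continue
            clash = set(literature_genes) & set(other.genes)
            if clash:
                raise ValueError(
                    f"literature genes {sorted(clash)} already in the "
                    f"{other.cytokine} signature; disjointness would break"
                )
    genes = list(signature.genes)
    prov = dict(signature.provenance)
    for g in literature_genes:
        if g not in prov:
            genes.append(g)
            prov[g] = "literature"
    return ResponderSignature(signature.cytokine, genes, prov)


def derive_signatures(
    stim_table: StimDegTable,
    spatial_degs: dict[str, list[str]],
    cytokines=("IFNG", "IL13", "IL17A"),
    fc_thresholds: dict[str, float] | None = None,
    p_cut: float = DEFAULT_P_CUT,
    padj_cut: float = DEFAULT_PADJ_CUT,
    literature_genes: dict[str, list[str]] | None = None,
) -> dict[str, ResponderSignature]:
    """Full cascade: filter → spatial intersection → cross-signature
    purification → literature supplementation."""
    candidates = []
    for cyt in cytokines:
        stim = filter_stim_deg(stim_table, cyt, fc_thresholds, p_cut, padj_cut)
        genes = intersect_with_spatial(stim, spatial_degs.get(cyt, []), cyt)
        candidates.append(ResponderSignature(cyt, genes))
    purified = purify_signatures(candidates)
    if literature_genes:
        for i, sig in enumerate(purified):
            extra = literature_genes.get(sig.cytokine)
            if extra:
                purified[i] = add_literature_genes(
                    sig, extra, other_signatures=purified
                )
    return {sig.cytokine: sig for sig in purified}


def save_signatures(signatures: dict[str, ResponderSignature], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.as_dict() for k, v in signatures.items()}, fh, indent=2)


def load_signatures(path) -> dict[str, ResponderSignature]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        k: ResponderSignature(v["cytokine"], v["genes"], v.get("provenance", {}))
        for k, v in raw.items()
    }
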