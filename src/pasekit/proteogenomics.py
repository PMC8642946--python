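"""Proteogenomic enumeration of allele-distinguishing (variant) peptides.

Missense variants between the reference strain (B allele, GRCm38/UniProt
sequence) and the alternate strain (D allele) are applied to reference
protein sequences; in-silico tryptic digestion of both allelic forms yields
variant peptide pairs — equal-length peptides differing exactly at the
variant site(s) — which are what allows a TMT experiment to distinguish the
two alleles of a protein.  Substitutions that create or destroy a K/R
cleavage site break the pairing and are emitted as singletons with a reason
code.  Identified peptide sequences are then assigned to B-allele, D-allele,
or non-variant, and pairs with both alleles detected are marked complete.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: strips TMT/PTM annotations like "C[+57.021]" or "M(ox)" and lowercase tags
_MOD_PATTERN = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Z]")

VARIANT_COLUMNS = ("protein", "position", "ref", "alt")


def strip_modifications(sequence: str) -> str:
    """Remove bracketed/parenthesized modification strings and non-residue chars."""
    return _MOD_PATTERN.sub("", sequence)


def read_fasta(path) -> dict[str, str]:
    """Accession -> sequence (first whitespace-delimited token of the header)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records.items()),
        str(path), "fasta")


def _check_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing column(s): {sorted(missing)}")
    bad = ~(variants["ref"].isin(STANDARD_AA) & variants["alt"].isin(STANDARD_AA))
    if bad.any():
        raise ValueError(
            f"non-standard amino acids in variant rows {variants.index[bad].tolist()}")
    if (variants["ref"] == variants["alt"]).any():
        raise ValueError("variant with ref == alt")
    return variants


def apply_missense_variants(reference: Mapping[str, str],
                            variants: pd.DataFrame) -> dict[str, str]:
    """Customized database: reference entries plus one alternate per (protein, variant).

    Alternate headers are ``{accession}|{ref}{position}{alt}`` (1-based
    protein coordinates).  Every variant's reference residue must match the
    sequence at its position.
    """
    if variants.empty:
        return dict(reference)
    _check_variants(variants)
    out = dict(reference)
    for row in variants.itertuples():
        acc, pos, ref, alt = row.protein, int(row.position), row.ref, row.alt
        if acc not in reference:
            raise ValueError(f"variant references unknown protein {acc!r}")
        seq = reference[acc]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{acc}: position {pos} outside protein length {len(seq)}")
        if seq[pos - 1] != ref:
            raise ValueError(
                f"{acc}: reference residue mismatch at position {pos} "
                f"(sequence has {seq[pos - 1]!r}, variant claims {ref!r})")
        out[f"{acc}|{ref}{pos}{alt}"] = seq[: pos - 1] + alt + seq[pos:]
    return out


@dataclass(frozen=True)
class Peptide:
    """One tryptic product with 0-based half-open protein coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def tryptic_digest(sequence: str, missed_cleavages: int = 2, min_len: int = 6,
                   max_len: int = 50, proline_rule: bool = True,
                   on_nonstandard: str = "error") -> list[Peptide]:
    """In-silico trypsin digest: cleave after K/R, suppressed before P.

    Returns all products with at most ``missed_cleavages`` internal sites and
    length within [min_len, max_len], in N-to-C order.  ``on_nonstandard``
    is 'error' or 'skip' (return empty list) for sequences with non-standard
    residues.
    """
    if not sequence:
        raise ValueError("empty sequence")
    nonstandard = set(sequence) - STANDARD_AA
    if nonstandard:
        if on_nonstandard == "skip":
            return []
        raise ValueError(f"non-standard residue(s) {sorted(nonstandard)}")
    # cut points between i-1 and i (0-based), plus both termini
    cuts = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            cuts.append(i)
    cuts.append(len(sequence))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[a], cuts[b]
            if min_len <= end - start <= max_len:
                peptides.append(Peptide(sequence[start:end], start, end, b - a - 1))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def enumerate_variant_peptide_pairs(reference: Mapping[str, str],
                                    variants: pd.DataFrame,
                                    missed_cleavages: int = 2, min_len: int = 6,
                                    max_len: int = 50, proline_rule: bool = True
                                    ) -> pd.DataFrame:
    """Pair every variant-covering tryptic peptide of the alternate protein
    with its reference counterpart.

    All variants of a protein are substituted together, so peptides spanning
    several variants become multi-variant pairs (flagged).  When a
    substitution creates or destroys a cleavage site, the alternate peptide
    has no same-span reference counterpart and is emitted as a singleton with
    reason ``site_change``.  Pairs differing only by isoleucine/leucine are
    flagged MS-indistinguishable rather than dropped.

    Output is sorted by (accession, first variant position, peptide start);
    columns: pair_id, protein, gene, b_peptide, d_peptide, start, end,
    variant_positions, n_variants, status, reason, multi_variant,
    il_indistinguishable.
    """
    if variants.empty:
        return pd.DataFrame(columns=[
            "pair_id", "protein", "gene", "b_peptide", "d_peptide", "start", "end",
            "variant_positions", "n_variants", "status", "reason", "multi_variant",
            "il_indistinguishable"])
    _check_variants(variants)
    digest_kw = dict(missed_cleavages=missed_cleavages, min_len=min_len,
                     max_len=max_len, proline_rule=proline_rule)
    rows = []
    for acc in sorted(variants["protein"].unique()):
        sub = variants[variants["protein"] == acc].sort_values("position")
        ref_seq = reference.get(acc)
        if ref_seq is None:
            raise ValueError(f"variant references unknown protein {acc!r}")
        alt_seq = list(ref_seq)
        positions = []
        for row in sub.itertuples():
            pos = int(row.position)
            if not 1 <= pos <= len(ref_seq):
                raise ValueError(f"{acc}: position {pos} out of range")
            if ref_seq[pos - 1] != row.ref:
                raise ValueError(f"{acc}: ref mismatch at position {pos}")
            alt_seq[pos - 1] = row.alt
            positions.append(pos)
        alt_seq = "".join(alt_seq)
        gene = str(sub["gene"].iloc[0]) if "gene" in sub.columns else ""
        ref_by_span = {(p.start, p.end): p for p in tryptic_digest(ref_seq, **digest_kw)}
        for pep in tryptic_digest(alt_seq, **digest_kw):
            covered = [p for p in positions if pep.start < p <= pep.end]
            if not covered:
                continue
            mate = ref_by_span.get((pep.start, pep.end))
            if mate is None or len(mate.sequence) != len(pep.sequence):
                rows.append(dict(protein=acc, gene=gene, b_peptide="",
                                 d_peptide=pep.sequence, start=pep.start,
                                 end=pep.end, variant_positions=covered,
                                 status="singleton", reason="site_change"))
                continue
            diff = [i for i, (x, y) in enumerate(zip(mate.sequence, pep.sequence))
                    if x != y]
            if len(diff) != len(covered):
                # substitution silenced by another variant landing on a cut site
                rows.append(dict(protein=acc, gene=gene, b_peptide=mate.sequence,
                                 d_peptide=pep.sequence, start=pep.start,
                                 end=pep.end, variant_positions=covered,
                                 status="singleton", reason="site_change"))
                continue
            il_only = all({mate.sequence[i], pep.sequence[i]} == {"I", "L"}
                          for i in diff)
            rows.append(dict(protein=acc, gene=gene, b_peptide=mate.sequence,
                             d_peptide=pep.sequence, start=pep.start, end=pep.end,
                             variant_positions=covered, status="paired", reason="",
                             il_indistinguishable=il_only))
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=[
            "pair_id", "protein", "gene", "b_peptide", "d_peptide", "start", "end",
            "variant_positions", "n_variants", "status", "reason", "multi_variant",
            "il_indistinguishable"])
    out["n_variants"] = out["variant_positions"].str.len()
    out["multi_variant"] = out["n_variants"] > 1
    if "il_indistinguishable" not in out.columns:
        out["il_indistinguishable"] = False
    out["il_indistinguishable"] = (
        out["il_indistinguishable"].map(lambda v: bool(v) if v == v else False))
    out["first_position"] = out["variant_positions"].apply(lambda p: p[0])
    out = out.sort_values(["protein", "first_position", "start"],
                          kind="stable").reset_index(drop=True)
    out.insert(0, "pair_id", [f"vp_{i:05d}" for i in range(len(out))])
    out["variant_positions"] = out["variant_positions"].apply(
        lambda p: ";".join(str(x) for x in p))
    return out.drop(columns=["first_position"])


def match_identified_peptides(quant: pd.DataFrame, pairs: pd.DataFrame
                              ) -> pd.DataFrame:
    """Assign identified peptide sequences to alleles and attach abundances.

    ``quant`` has a ``peptide`` column (modifications are stripped before
    matching) followed by per-sample abundance columns.  Returns the pair
    table in long form (pair_id, allele, peptide, plus samples) restricted to
    detected allele peptides, with ``complete`` marking pairs where both
    alleles were detected.  A sequence matching both alleles of one pair is
    an upstream integrity violation and raises.
    """
    paired = pairs[pairs["status"] == "paired"]
    b_map: dict[str, list[str]] = {}
    d_map: dict[str, list[str]] = {}
    for row in paired.itertuples():
        if row.b_peptide == row.d_peptide:
            raise ValueError(f"pair {row.pair_id}: B and D sequences identical")
        b_map.setdefault(row.b_peptide, []).append(row.pair_id)
        d_map.setdefault(row.d_peptide, []).append(row.pair_id)
    both = set(b_map) & set(d_map)
    if both:
        raise ValueError(
            f"sequence(s) match both a B and a D allele: {sorted(both)[:5]}")

    sample_cols = [c for c in quant.columns if c != "peptide"]
    rows = []
    for row in quant.itertuples():
        seq = strip_modifications(str(row.peptide))
        for allele, mapping in (("B", b_map), ("D", d_map)):
            for pid in mapping.get(seq, []):
                rows.append({"pair_id": pid, "allele": allele, "peptide": seq,
                             **{c: getattr(row, c) for c in sample_cols}})
    out = pd.DataFrame(rows, columns=["pair_id", "allele", "peptide", *sample_cols])
    detected = out.groupby("pair_id")["allele"].nunique() if len(out) else pd.Series(dtype=int)
    complete = set(detected[detected == 2].index)
    out["complete"] = out["pair_id"].isin(complete)
    out.attrs["n_complete_pairs"] = len(complete)
    out = out.sort_values(["pair_id", "allele"], kind="stable").reset_index(drop=True)
    return out
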