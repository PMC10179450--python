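"""CDS extraction and relative synonymous codon usage (RSCU).

RSCU for a codon ``c`` of an amino acid with ``k`` synonymous codons is
``count(c) * k / sum(counts over the family)``: 1 means uniform usage
within the family, >1 preferential usage. Codon counts are taken over the
genomic (DNA) coding sequences as annotated; RNA-edited codons are counted
as written in DNA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CDS:
    gene: str
    seq: str  # spliced, strand-corrected, 5'->3' DNA
    partial: bool = False  # length not divisible by 3 (trailing codon dropped)
    trans_spliced_part: bool = False


def extract_cds(genbank_path, min_length: int = 3) -> list[CDS]:
    """Spliced, strand-corrected CDS sequences from a GenBank flat file.

    join()/complement() locations are resolved; duplicated gene copies are
    all returned. Trans-spliced genes are assembled only when annotated as
    a single joined feature — otherwise each part is emitted separately and
    flagged. CDSs whose length is not divisible by 3 are flagged and their
    trailing partial codon is dropped by :func:`compute_rscu`.
    """
    out: list[CDS] = []
    for record in SeqIO.parse(str(genbank_path), "genbank"):
        seen_genes: dict[str, int] = {}
        for feat in record.features:
            if feat.type != "CDS":
                continue
            gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
            try:
                seq = str(feat.extract(record.seq)).upper()
            except Exception as exc:  # malformed location
                logger.warning("skipping CDS %s: %s", gene, exc)
                continue
            if len(seq) < min_length:
                logger.warning("skipping CDS %s: too short (%d bp)", gene, len(seq))
                continue
            partial = len(seq) % 3 != 0
            if partial:
                logger.warning("CDS %s length %d not divisible by 3", gene, len(seq))
            trans_part = "trans_splicing" in feat.qualifiers or (
                feat.qualifiers.get("exception", [""])[0] == "trans-splicing"
                and len(feat.location.parts) == 1
            )
            seen_genes[gene] = seen_genes.get(gene, 0) + 1
            out.append(CDS(gene=gene, seq=seq, partial=partial, trans_spliced_part=trans_part))
    return out


def _codon_families(table_id: int, include_stop: bool) -> dict[str, str]:
    """codon (DNA) -> amino-acid letter (or '*' for stop)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fam = dict(table.forward_table)
    if include_stop:
        for c in table.stop_codons:
            fam[c] = "*"
    else:
        for c in table.stop_codons:
            fam.pop(c, None)
    return fam


def compute_rscu(
    cds_list,
    include_stop: bool = False,
    genetic_code: int = 1,
) -> pd.DataFrame:
    """Codon counts and RSCU over a set of CDS sequences.

    Returns a DataFrame with one row per codon of the genetic code
    (stop codons only with ``include_stop``), columns ``codon`` (RNA
    alphabet), ``dna_codon``, ``amino_acid``, ``count``, ``rscu``. Codons
    containing N are skipped; a trailing partial codon is ignored. Families
    with zero total count get RSCU NaN.
    """
    seqs = [c.seq if isinstance(c, CDS) else str(c) for c in cds_list]
    if not seqs:
        raise ValueError("compute_rscu: empty CDS list")
    families = _codon_families(genetic_code, include_stop)
    counts = {c: 0 for c in families}
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
            elif "N" not in codon and codon not in families:
                # stop codon while stops are excluded, or ambiguous base
                continue
    fam_totals: dict[str, int] = {}
    fam_sizes: dict[str, int] = {}
    for codon, aa in families.items():
        fam_totals[aa] = fam_totals.get(aa, 0) + counts[codon]
        fam_sizes[aa] = fam_sizes.get(aa, 0) + 1
    rows = []
    for codon in sorted(families):
        aa = families[codon]
        total = fam_totals[aa]
        k = fam_sizes[aa]
        rscu = counts[codon] * k / total if total > 0 else float("nan")
        rows.append(
            {
                "codon": codon.replace("T", "U"),
                "dna_codon": codon,
                "amino_acid": aa,
                "count": counts[codon],
                "rscu": rscu,
            }
        )
    return pd.DataFrame(rows)
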