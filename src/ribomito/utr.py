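"""5'UTR feature extraction.

Extracts spliced 5' untranslated regions from a GTF/FASTA annotation pair
and computes the sequence features used by the translational-efficiency
association analysis: UTR length, GC content, and presence of a 5'-terminal
oligopyrimidine (TOP) motif.

Coordinates follow the GTF convention (1-based, inclusive) on disk and are
converted to half-open 0-based intervals internally; the conversion is
localised to :func:`extract_five_prime_utrs`.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PYRIMIDINES = frozenset("CTct")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T), case-insensitive; N is excluded from the
    denominator.  Returns NaN for an empty or all-N sequence (callers treat
    NaN as the "undefined" flag)."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return float("nan")
    return gc / denom


def detect_top_motif(sequence: str, min_pyr: int = 4, max_pyr: int = 15) -> bool:
    """True iff the sequence starts with C followed by an uninterrupted run
    of ``min_pyr``-``max_pyr`` pyrimidines (C/T).

    This is the canonical 5'TOP description: a cap-adjacent cytidine
    followed by a short pyrimidine tract.  The run is counted after the
    leading C and terminates at the first purine (or end of sequence).
    """
    if not sequence or sequence[0].upper() != "C":
        return False
    run = 0
    for base in sequence[1:]:
        if base in PYRIMIDINES:
            run += 1
            if run > max_pyr:
                return False
        else:
            break
    return run >= min_pyr


@dataclass
class UTRSet:
    """Per-transcript 5'UTR records plus extraction bookkeeping.

    ``records`` columns: transcript_id, sequence, length, gc, has_top,
    undefined (True when the UTR is empty so gc is flagged undefined).
    """

    records: pd.DataFrame
    n_no_cds: int = 0

    def write_tsv(self, path) -> None:
        out = self.records.copy()
        # fraction internally, percentage in written output
        out["gc_percent"] = out["gc"] * 100.0
        out.drop(columns=["gc"]).to_csv(path, sep="\t", index=False)


def _utr_record(transcript_id: str, sequence: str,
                min_pyr: int = 4, max_pyr: int = 15) -> dict:
    return {
        "transcript_id": transcript_id,
        "sequence": sequence,
        "length": len(sequence),
        "gc": gc_content(sequence),
        "has_top": detect_top_motif(sequence, min_pyr, max_pyr),
        "undefined": len(sequence) == 0 or np.isnan(gc_content(sequence)),
    }


def extract_five_prime_utrs(gtf_path, genome_fasta_path,
                            min_pyr: int = 4, max_pyr: int = 15) -> UTRSet:
    """Extract spliced 5'UTR sequences for every transcript with a CDS.

    For each transcript the 5'UTR is the exonic sequence strictly 5' of the
    first CDS base, spliced in transcript order; minus-strand transcripts
    are reverse-complemented.  Transcripts without any CDS feature are
    skipped and counted in ``UTRSet.n_no_cds``.

    Raises
    ------
    InputError
        If a chromosome named in the GTF is absent from the FASTA, or a CDS
        interval is not contained in the transcript's exons.
    """
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gtf_path), tmp.name, force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
        fasta = Fasta(str(genome_fasta_path))

        exons_by_tx: dict[str, list] = {}
        cds_by_tx: dict[str, list] = {}
        strand_by_tx: dict[str, str] = {}
        chrom_by_tx: dict[str, str] = {}
        for feat in db.all_features():
            if feat.featuretype not in ("exon", "CDS"):
                continue
            tx = feat.attributes.get("transcript_id", [None])[0]
            if tx is None:
                raise InputError(f"feature at {feat.seqid}:{feat.start} lacks transcript_id")
            strand_by_tx[tx] = feat.strand
            chrom_by_tx[tx] = feat.seqid
            # GTF 1-based inclusive -> half-open 0-based
            iv = (feat.start - 1, feat.end)
            target = exons_by_tx if feat.featuretype == "exon" else cds_by_tx
            target.setdefault(tx, []).append(iv)

        rows = []
        n_no_cds = 0
        for tx in sorted(exons_by_tx):
            if tx not in cds_by_tx:
                n_no_cds += 1
                continue
            chrom = chrom_by_tx[tx]
            if chrom not in fasta:
                raise InputError(f"chromosome {chrom!r} absent from FASTA")
            exons = sorted(exons_by_tx[tx])
            cds = sorted(cds_by_tx[tx])
            for cs, ce in cds:
                if not any(es <= cs and ce <= ee for es, ee in exons):
                    raise InputError(
                        f"malformed annotation: CDS [{cs + 1}, {ce}] of {tx} "
                        "is not contained in any exon"
                    )
            strand = strand_by_tx[tx]
            if strand == "+":
                cds_first = cds[0][0]
                pieces = [
                    str(fasta[chrom][s:min(e, cds_first)])
                    for s, e in exons if s < cds_first
                ]
                utr = "".join(pieces)
            else:
                cds_last = cds[-1][1]
                pieces = [
                    str(fasta[chrom][max(s, cds_last):e])
                    for s, e in exons if e > cds_last
                ]
                utr = reverse_complement("".join(pieces))
            rows.append(_utr_record(tx, utr.upper(), min_pyr, max_pyr))

    records = pd.DataFrame(
        rows, columns=["transcript_id", "sequence", "length", "gc",
                       "has_top", "undefined"],
    )
    return UTRSet(records=records, n_no_cds=n_no_cds)
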