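"""Loading (or fetching) the real reference inputs used by integration checks.

Reference sequences and structures are looked up first under
``data/reference/`` in the repository, then fetched from the public archives
with a short timeout.  Nothing is bundled: when neither source is available
the loader raises, and the calling test reports the failure honestly.
"""

from __future__ import annotations

import io
import urllib.request
from pathlib import Path

DATA_DIR = Path(__file__).resolve().parents[1] / "data" / "reference"
TIMEOUT_S = 15

SEQUENCE_SOURCES = {
    # RefSeq proteins via NCBI efetch
    "NP_035997.1": ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
                    "?db=protein&id=NP_035997.1&rettype=fasta&retmode=text"),
    "NP_000432.1": ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
                    "?db=protein&id=NP_000432.1&rettype=fasta&retmode=text"),
    # UniProt: mouse and human AP-2 mu2 (AP2M1)
    "P84091": "https://rest.uniprot.org/uniprotkb/P84091.fasta",
    "Q96CW1": "https://rest.uniprot.org/uniprotkb/Q96CW1.fasta",
}
STRUCTURE_SOURCES = {
    "6bnt": "https://files.rcsb.org/download/6BNT.pdb",
}


def _fetch(url: str) -> str:
    with urllib.request.urlopen(url, timeout=TIMEOUT_S) as response:
        return response.read().decode()


def load_reference_protein(accession: str):
    """A reference protein sequence from data/reference/ or the archives."""
    from Bio import SeqIO

    from pendock.sequences import ProteinSequence

    local = DATA_DIR / f"{accession}.fasta"
    if local.exists():
        text = local.read_text()
    else:
        try:
            text = _fetch(SEQUENCE_SOURCES[accession])
        except Exception as exc:
            raise RuntimeError(
                f"reference sequence {accession} unavailable: not in {local} "
                f"and fetch failed ({exc})"
            ) from exc
    record = next(SeqIO.parse(io.StringIO(text), "fasta"))
    return ProteinSequence(accession, str(record.seq).upper())


def load_reference_structure(pdb_id: str):
    """A reference structure (PDB format) from data/reference/ or RCSB."""
    from pendock.structure import parse_structure

    local = DATA_DIR / f"{pdb_id}.pdb"
    if local.exists():
        return parse_structure(local)
    try:
        text = _fetch(STRUCTURE_SOURCES[pdb_id])
    except Exception as exc:
        raise RuntimeError(
            f"reference structure {pdb_id} unavailable: not in {local} "
            f"and fetch failed ({exc})"
        ) from exc
    return parse_structure(text, fmt="pdb")
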