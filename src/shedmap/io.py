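"""File I/O: FASTA, MGF peak lists and TSV tables.

All tables are UTF-8 tab-separated with a header row. FASTA goes through
Biopython (wrapped at 60 columns on write), MGF through pyteomics.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .fragments import Peak, Spectrum
from .proteolysis import PeptideMatch, ProteinRecord


# --- FASTA ------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def load_reference_protein(name: str = "pthr1_ecd_synthetic") -> ProteinRecord:
    """A bundled reference sequence (see data/ for provenance notes)."""
    ref = importlib.resources.files("shedmap.data").joinpath(f"{name}.fasta")
    with importlib.resources.as_file(ref) as path:
        return read_fasta(path)[0]


# --- MGF --------------------------------------------------------------------

def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            peaks = [
                Peak(float(m), float(i))
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            ]
            spectra.append(
                Spectrum(
                    peaks,
                    precursor_charge=charge,
                    peptide=params.get("seq"),
                    label=params.get("title", ""),
                )
            )
    if not spectra:
        raise ValueError(f"no spectra in {path}")
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.label, "charge": s.precursor_charge}
        if s.peptide:
            params["seq"] = s.peptide
        entries.append(
            {
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_peak_table(path) -> Spectrum:
    """Two-column m/z-intensity TSV to a Spectrum."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("mz", "intensity"):
        if col not in frame.columns:
            raise KeyError(f"missing required column {col!r}")
    return Spectrum.from_arrays(frame["mz"], frame["intensity"], label=str(path))


# --- peptide tables ---------------------------------------------------------

PEPTIDE_COLUMNS = ("peptide", "protein_id", "protease")


def read_peptide_table(path) -> list[PeptideMatch]:
    """TSV with columns peptide, protein_id, protease (+ optional start/end).

    When start/end are absent or empty a placeholder 1..len span is stored;
    spans are verified against the protein sequence and re-mapped by
    occurrence search downstream (`cleavage.locate_peptides`), so the
    placeholder never leaks into site calls.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in PEPTIDE_COLUMNS:
        if col not in frame.columns:
            raise KeyError(f"missing required column {col!r}")
    has_span = "start" in frame.columns and "end" in frame.columns
    matches = []
    for _, row in frame.iterrows():
        pep = str(row["peptide"])
        if has_span and pd.notna(row["start"]) and pd.notna(row["end"]):
            start, end = int(row["start"]), int(row["end"])
        else:
            start, end = 1, len(pep)  # placeholder span; remapped on use
        matches.append(
            PeptideMatch(str(row["protein_id"]), start, end, pep, str(row["protease"]))
        )
    return matches


def write_peptide_table(matches: list[PeptideMatch], path) -> None:
    pd.DataFrame(
        {
            "peptide": [m.peptide for m in matches],
            "protein_id": [m.protein_id for m in matches],
            "protease": [m.protease for m in matches],
            "start": [m.start for m in matches],
            "end": [m.end for m in matches],
        }
    ).to_csv(path, sep="\t", index=False)


def write_site_calls(calls, path) -> None:
    pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "site": [c.site for c in calls],
            "concordant": [c.concordant for c in calls],
            "n_side_peptides": [";".join(c.n_side_peptides) for c in calls],
            "c_side_peptides": [";".join(c.c_side_peptides) for c in calls],
            "proteases": [";".join(sorted(c.proteases)) for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


# --- intensity matrices -----------------------------------------------------

def read_intensity_matrix(matrix_path, groups_path):
    """Protein x sample TSV plus a YAML/JSON sample->group sidecar."""
    import yaml

    from .proteome import IntensityMatrix

    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    with open(groups_path) as fh:
        groups = yaml.safe_load(fh)
    if not isinstance(groups, dict):
        raise ValueError("group map must be a mapping of sample -> group")
    return IntensityMatrix(frame, groups)


def write_intensity_matrix(matrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")
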