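"""Built-in lookup tables: residue alphabets, modified-residue parents, vdW radii,
and per-residue reference maximum accessible surface areas."""

# 20 standard amino acids, three-letter -> one-letter
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Common chemically modified residues mapped to their parent amino acid.
# Anything not listed here (and not standard) becomes 'X'.
MODIFIED_TO_PARENT = {
    "MSE": "M",  # selenomethionine
    "CSO": "C", "CSS": "C", "CME": "C", "OCS": "C", "CSD": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y",
    "HYP": "P", "MLY": "K", "KCX": "K", "LLP": "K",
    "PCA": "Q", "FME": "M", "MLE": "L", "AIB": "A",
    "SEC": "C", "PYL": "K",
}

# Ribonucleotide residue names (standard + common modified bases)
RNA_RESNAMES = {
    "A", "C", "G", "U", "I", "N",
    "1MA", "5MC", "OMC", "7MG", "OMG", "2MG", "M2G", "H2U",
    "PSU", "5MU", "4SU", "YG", "QUO", "MIA",
}
RNA_ONE = {"A": "A", "C": "C", "G": "G", "U": "U"}

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

ION_RESNAMES = {
    "NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "FE2", "CU",
    "CO", "NI", "CD", "HG", "BR", "IOD", "CS", "LI", "SR", "BA",
    "SO4", "PO4", "NO3", "ACT", "GOL", "EDO", "PEG",
}

# PSI-BLAST PSSM column order (the 20 score columns of the ASCII matrix)
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWVY"

# Van der Waals radii by element (Angstrom); fallback used for rare elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90,
}
VDW_DEFAULT = 1.80

# Theoretical maximum accessible surface areas per residue type (A^2),
# Tien et al. 2013 values; used to express per-residue SASA in percent.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
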