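"""Brainnetome-style ROI lookup table.

The default parcellation is the 246-region Brainnetome scheme: 210 cortical
subregions (123 left/right pairs over frontal, temporal, parietal, insular,
limbic and occipital lobes) followed by 36 subcortical subregions (amygdala,
hippocampus, basal ganglia, thalamus).  Indices are 1-based; odd = left
hemisphere, even = right.  The table is generated from the subregion
structure below rather than shipped as a data file; user atlases load from
TSV.  MNI coordinates are optional and only required by the visualisation
exporters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AtlasTable", "default_atlas", "load_atlas"]

# (gyrus abbrev, gyrus name, lobe, cortical?, [(subregion abbrev, subregion name), ...])
_STRUCTURE = [
    ("SFG", "superior frontal gyrus", "frontal lobe", True, [
        ("A8m", "Medial Brodmann area 8"),
        ("A8dl", "Dorsolateral Brodmann area 8"),
        ("A9l", "Lateral Brodmann area 9"),
        ("A6dl", "Dorsolateral Brodmann area 6"),
        ("A6m", "Medial Brodmann area 6"),
        ("A9m", "Medial Brodmann area 9"),
        ("A10m", "Medial Brodmann area 10"),
    ]),
    ("MFG", "middle frontal gyrus", "frontal lobe", True, [
        ("A9/46d", "Dorsal Brodmann area 9/46"),
        ("IFJ", "Inferior frontal junction"),
        ("A46", "Brodmann area 46"),
        ("A9/46v", "Ventral Brodmann area 9/46"),
        ("A8vl", "Ventrolateral Brodmann area 8"),
        ("A6vl", "Ventrolateral Brodmann area 6"),
        ("A10l", "Lateral Brodmann area 10"),
    ]),
    ("IFG", "inferior frontal gyrus", "frontal lobe", True, [
        ("A44d", "Dorsal Brodmann area 44"),
        ("IFS", "Inferior frontal sulcus"),
        ("A45c", "Caudal Brodmann area 45"),
        ("A45r", "Rostral Brodmann area 45"),
        ("A44op", "Opercular Brodmann area 44"),
        ("A44v", "Ventral Brodmann area 44"),
    ]),
    ("OrG", "orbital gyrus", "frontal lobe", True, [
        ("A14m", "Medial Brodmann area 14"),
        ("A12/47o", "Orbital Brodmann area 12/47"),
        ("A11l", "Lateral Brodmann area 11"),
        ("A11m", "Medial Brodmann area 11"),
        ("A13", "Brodmann area 13"),
        ("A12/47l", "Lateral Brodmann area 12/47"),
    ]),
    ("PrG", "precentral gyrus", "frontal lobe", True, [
        ("A4hf", "Brodmann area 4 (head and face region)"),
        ("A6cdl", "Caudal dorsolateral Brodmann area 6"),
        ("A4ul", "Brodmann area 4 (upper limb region)"),
        ("A4t", "Brodmann area 4 (trunk region)"),
        ("A4tl", "Brodmann area 4 (tongue and larynx region)"),
        ("A6cvl", "Caudal ventrolateral Brodmann area 6"),
    ]),
    ("PCL", "paracentral lobule", "frontal lobe", True, [
        ("A1/2/3ll", "Brodmann area 1/2/3 (lower limb region)"),
        ("A4ll", "Brodmann area 4 (lower limb region)"),
    ]),
    ("STG", "superior temporal gyrus", "temporal lobe", True, [
        ("A38m", "Medial Brodmann area 38"),
        ("A41/42", "Brodmann area 41/42"),
        ("TE1.0/TE1.2", "TE1.0 and TE1.2"),
        ("A22c", "Caudal Brodmann area 22"),
        ("A38l", "Lateral Brodmann area 38"),
        ("A22r", "Rostral Brodmann area 22"),
    ]),
    ("MTG", "middle temporal gyrus", "temporal lobe", True, [
        ("A21c", "Caudal Brodmann area 21"),
        ("A21r", "Rostral Brodmann area 21"),
        ("A37dl", "Dorsolateral Brodmann area 37"),
        ("aSTS", "Anterior superior temporal sulcus"),
    ]),
    ("ITG", "inferior temporal gyrus", "temporal lobe", True, [
        ("A20iv", "Intermediate ventral Brodmann area 20"),
        ("A37elv", "Extreme lateroventral Brodmann area 37"),
        ("A20r", "Rostral Brodmann area 20"),
        ("A20il", "Intermediate lateral Brodmann area 20"),
        ("A37vl", "Ventrolateral Brodmann area 37"),
        ("A20cl", "Caudolateral Brodmann area 20"),
        ("A20cv", "Caudoventral Brodmann area 20"),
    ]),
    ("FuG", "fusiform gyrus", "temporal lobe", True, [
        ("A20rv", "Rostroventral Brodmann area 20"),
        ("A37mv", "Medioventral Brodmann area 37"),
        ("A37lv", "Lateroventral Brodmann area 37"),
    ]),
    ("PhG", "parahippocampal gyrus", "temporal lobe", True, [
        ("A35/36r", "Rostral Brodmann area 35/36"),
        ("A35/36c", "Caudal Brodmann area 35/36"),
        ("TL", "Lateral posterior parahippocampal area TL"),
        ("A28/34", "Brodmann area 28/34 (entorhinal cortex)"),
        ("TI", "Temporal agranular insular area TI"),
        ("TH", "Medial posterior parahippocampal area TH"),
    ]),
    ("pSTS", "posterior superior temporal sulcus", "temporal lobe", True, [
        ("rpSTS", "Rostroposterior superior temporal sulcus"),
        ("cpSTS", "Caudoposterior superior temporal sulcus"),
    ]),
    ("SPL", "superior parietal lobule", "parietal lobe", True, [
        ("A7r", "Rostral Brodmann area 7"),
        ("A7c", "Caudal Brodmann area 7"),
        ("A5l", "Lateral Brodmann area 5"),
        ("A7pc", "Postcentral Brodmann area 7"),
        ("A7ip", "Intraparietal Brodmann area 7"),
    ]),
    ("IPL", "inferior parietal lobule", "parietal lobe", True, [
        ("A39c", "Caudal Brodmann area 39"),
        ("A39rd", "Rostrodorsal Brodmann area 39"),
        ("A40rd", "Rostrodorsal Brodmann area 40"),
        ("A40c", "Caudal Brodmann area 40"),
        ("A39rv", "Rostroventral Brodmann area 39"),
        ("A40rv", "Rostroventral Brodmann area 40"),
    ]),
    ("Pcun", "precuneus", "parietal lobe", True, [
        ("A7m", "Medial Brodmann area 7"),
        ("A5m", "Medial Brodmann area 5"),
        ("dmPOS", "Dorsomedial parieto-occipital sulcus"),
        ("A31", "Brodmann area 31"),
    ]),
    ("PoG", "postcentral gyrus", "parietal lobe", True, [
        ("A1/2/3ulhf", "Brodmann area 1/2/3 (upper limb, head and face region)"),
        ("A1/2/3tonIa", "Brodmann area 1/2/3 (tongue and larynx region)"),
        ("A2", "Brodmann area 2"),
        ("A1/2/3tru", "Brodmann area 1/2/3 (trunk region)"),
    ]),
    ("INS", "insular gyrus", "insular lobe", True, [
        ("G", "Hypergranular insula"),
        ("vIa", "Ventral agranular insula"),
        ("dIa", "Dorsal agranular insula"),
        ("vId/vIg", "Ventral dysgranular and granular insula"),
        ("dIg", "Dorsal granular insula"),
        ("dId", "Dorsal dysgranular insula"),
    ]),
    ("CG", "cingulate gyrus", "limbic lobe", True, [
        ("A23d", "Dorsal Brodmann area 23"),
        ("A24rv", "Rostroventral Brodmann area 24"),
        ("A32p", "Pregenual Brodmann area 32"),
        ("A23v", "Ventral Brodmann area 23"),
        ("A24cd", "Caudodorsal Brodmann area 24"),
        ("A23c", "Caudal Brodmann area 23"),
        ("A32sg", "Subgenual Brodmann area 32"),
    ]),
    ("MVOcC", "ventromedial occipital cortex", "occipital lobe", True, [
        ("cLinG", "Caudal lingual gyrus"),
        ("rCunG", "Rostral cuneus gyrus"),
        ("cCunG", "Caudal cuneus gyrus"),
        ("rLinG", "Rostral lingual gyrus"),
        ("vmPOS", "Ventromedial parieto-occipital sulcus"),
    ]),
    ("LOcC", "lateral occipital cortex", "occipital lobe", True, [
        ("mOccG", "Middle occipital gyrus"),
        ("V5/MT+", "Area V5/MT+"),
        ("OPC", "Occipital polar cortex"),
        ("iOccG", "Inferior occipital gyrus"),
        ("msOccG", "Medial superior occipital gyrus"),
        ("lsOccG", "Lateral superior occipital gyrus"),
    ]),
    ("Amyg", "amygdala", "subcortical nuclei", False, [
        ("mAmyg", "Medial amygdala"),
        ("lAmyg", "Lateral amygdala"),
    ]),
    ("Hipp", "hippocampus", "subcortical nuclei", False, [
        ("rHipp", "Rostral hippocampus"),
        ("cHipp", "Caudal hippocampus"),
    ]),
    ("BG", "basal ganglia", "subcortical nuclei", False, [
        ("vCa", "Ventral caudate"),
        ("GP", "Globus pallidus"),
        ("NAC", "Nucleus accumbens"),
        ("vmPu", "Ventromedial putamen"),
        ("dCa", "Dorsal caudate"),
        ("dlPu", "Dorsolateral putamen"),
    ]),
    ("Tha", "thalamus", "subcortical nuclei", False, [
        ("mPFtha", "Medial prefrontal thalamus"),
        ("mPMtha", "Premotor thalamus"),
        ("Stha", "Sensory thalamus"),
        ("rTtha", "Rostral temporal thalamus"),
        ("PPtha", "Posterior parietal thalamus"),
        ("Otha", "Occipital thalamus"),
        ("cTtha", "Caudal temporal thalamus"),
        ("lPFtha", "Lateral prefrontal thalamus"),
    ]),
]

REQUIRED_COLUMNS = ("index", "abbreviation", "description")


@dataclass
class AtlasTable:
    """Validated ROI lookup table (1-based contiguous indices)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        idx = df["index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("atlas indices must be unique")
        if not np.array_equal(np.sort(idx), np.arange(1, len(idx) + 1)):
            raise ValueError("atlas indices must be contiguous from 1")
        self.table = df.sort_values("index").reset_index(drop=True)

    @property
    def n_roi(self) -> int:
        return len(self.table)

    @property
    def n_cortical(self) -> int:
        if "cortical" not in self.table.columns:
            raise ValueError("atlas has no cortical/subcortical annotation")
        return int(self.table["cortical"].sum())

    @property
    def n_subcortical(self) -> int:
        return self.n_roi - self.n_cortical

    def abbreviation(self, index: int) -> str:
        """Abbreviation for a 1-based ROI index."""
        return str(self.table.loc[index - 1, "abbreviation"])

    def description(self, index: int) -> str:
        return str(self.table.loc[index - 1, "description"])

    @property
    def has_coordinates(self) -> bool:
        return {"x", "y", "z"}.issubset(self.table.columns) and (
            self.table[["x", "y", "z"]].notna().all().all()
        )

    def coordinates(self) -> np.ndarray:
        if not self.has_coordinates:
            missing = (
                self.table["index"].tolist()
                if not {"x", "y", "z"}.issubset(self.table.columns)
                else self.table.loc[
                    self.table[["x", "y", "z"]].isna().any(axis=1), "index"
                ].tolist()
            )
            raise ValueError(f"atlas lacks MNI coordinates for ROIs: {missing}")
        return self.table[["x", "y", "z"]].to_numpy(float)


def default_atlas() -> AtlasTable:
    """The built-in 246-region table (210 cortical + 36 subcortical)."""
    rows = []
    idx = 1
    for g_abbr, g_name, lobe, cortical, subs in _STRUCTURE:
        for abbr, name in subs:
            for hemi in ("L", "R"):
                rows.append(
                    {
                        "index": idx,
                        "abbreviation": abbr,
                        "description": f"{name} in {g_name} of {lobe}",
                        "hemisphere": hemi,
                        "gyrus": g_abbr,
                        "lobe": lobe,
                        "cortical": cortical,
                    }
                )
                idx += 1
    return AtlasTable(pd.DataFrame(rows))


def load_atlas(path: str) -> AtlasTable:
    """Load and validate an atlas TSV (columns index/abbreviation/description,
    optional hemisphere/lobe/cortical/x/y/z)."""
    df = pd.read_csv(path, sep="\t")
    return AtlasTable(df)
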