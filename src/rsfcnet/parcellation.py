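"""Default brain parcellation: the 116-region AAL node set.

The AAL (Automated Anatomical Labeling) atlas parcellates the brain into 90
cerebral regions (45 homologous left/right pairs) and 26 cerebellar regions
(9 hemispheric pairs plus 8 vermis lobules).  Only the region label table is
bundled here — no atlas image — and its order fixes the canonical node order
used throughout the package: matrices are indexed 0-based in this order and
reports use these labels.
"""

from __future__ import annotations

_CEREBRAL_PAIRS = [
    ("PreC", "Precentral gyrus"),
    ("SFGdor", "Superior frontal gyrus (dorsolateral)"),
    ("ORBsup", "Superior frontal gyrus (orbital part)"),
    ("MFG", "Middle frontal gyrus"),
    ("ORBmid", "Middle frontal gyrus (orbital part)"),
    ("IFGoper", "Inferior frontal gyrus (opercular part)"),
    ("IFGtriang", "Inferior frontal gyrus (triangular part)"),
    ("ORBinf", "Inferior frontal gyrus (orbital part)"),
    ("ROL", "Rolandic operculum"),
    ("SMA", "Supplementary motor area"),
    ("OLF", "Olfactory cortex"),
    ("SFGmed", "Superior frontal gyrus (medial)"),
    ("ORBsupmed", "Superior frontal gyrus (medial orbital)"),
    ("REC", "Rectus gyrus"),
    ("INS", "Insula"),
    ("ACG", "Anterior cingulate and paracingulate gyri"),
    ("DCG", "Median cingulate and paracingulate gyri"),
    ("PCG", "Posterior cingulate gyrus"),
    ("HIP", "Hippocampus"),
    ("PHG", "Parahippocampal gyrus"),
    ("AMYG", "Amygdala"),
    ("CAL", "Calcarine fissure and surrounding cortex"),
    ("CUN", "Cuneus"),
    ("LING", "Lingual gyrus"),
    ("SOG", "Superior occipital gyrus"),
    ("MOG", "Middle occipital gyrus"),
    ("IOG", "Inferior occipital gyrus"),
    ("FFG", "Fusiform gyrus"),
    ("PostC", "Postcentral gyrus"),
    ("SPG", "Superior parietal gyrus"),
    ("IPL", "Inferior parietal lobule"),
    ("SMG", "Supramarginal gyrus"),
    ("ANG", "Angular gyrus"),
    ("PCUN", "Precuneus"),
    ("PCL", "Paracentral lobule"),
    ("CAU", "Caudate nucleus"),
    ("PUT", "Lenticular nucleus, putamen"),
    ("PAL", "Lenticular nucleus, pallidum"),
    ("THA", "Thalamus"),
    ("HES", "Heschl gyrus"),
    ("STG", "Superior temporal gyrus"),
    ("TPOsup", "Temporal pole: superior temporal gyrus"),
    ("MTG", "Middle temporal gyrus"),
    ("TPOmid", "Temporal pole: middle temporal gyrus"),
    ("ITG", "Inferior temporal gyrus"),
]

_CEREBELLAR_PAIRS = [
    ("Crus1", "Crus cerebelli I"),
    ("Crus2", "Crus cerebelli II"),
    ("CL3", "Cerebellar lobule III"),
    ("CL4_5", "Cerebellar lobule IV/V"),
    ("CL6", "Cerebellar lobule VI"),
    ("CL7b", "Cerebellar lobule VIIB"),
    ("CL8", "Cerebellar lobule VIII"),
    ("CL9", "Cerebellar lobule IX"),
    ("CL10", "Cerebellar lobule X"),
]

_VERMIS = [
    ("Vr1_2", "Vermis lobule I/II"),
    ("Vr3", "Vermis lobule III"),
    ("Vr4_5", "Vermis lobule IV/V"),
    ("Vr6", "Vermis lobule VI"),
    ("Vr7", "Vermis lobule VII"),
    ("Vr8", "Vermis lobule VIII"),
    ("Vr9", "Vermis lobule IX"),
    ("Vr10", "Vermis lobule X"),
]


def aal116_labels() -> list[str]:
    """Return the 116 AAL region labels in canonical order.

    Cerebral pairs first (left then right for each region), then the nine
    cerebellar hemispheric pairs, then the eight vermis lobules.
    """
    labels: list[str] = []
    for abbr, _ in _CEREBRAL_PAIRS + _CEREBELLAR_PAIRS:
        labels.append(f"{abbr}.L")
        labels.append(f"{abbr}.R")
    labels.extend(abbr for abbr, _ in _VERMIS)
    return labels


def aal116_table():
    """Return a pandas DataFrame of (label, abbreviation, hemisphere, region, lobe)."""
    import pandas as pd

    rows = []
    for abbr, name in _CEREBRAL_PAIRS:
        for hemi in ("L", "R"):
            rows.append((f"{abbr}.{hemi}", abbr, hemi, name, "cerebral"))
    for abbr, name in _CEREBELLAR_PAIRS:
        for hemi in ("L", "R"):
            rows.append((f"{abbr}.{hemi}", abbr, hemi, name, "cerebellar"))
    for abbr, name in _VERMIS:
        rows.append((abbr, abbr, "M", name, "cerebellar"))
    return pd.DataFrame(
        rows, columns=["label", "abbreviation", "hemisphere", "region", "lobe"]
    )


N_NODES = 116
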