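"""MedDRA preferred-term → system-organ-class resolution.

MedDRA itself is licensed and cannot ship with the package, so the primary
interface is a user-supplied two-column delimited file (PT, primary SOC).
A small toy ontology covering the vocabulary used by the bundled synthetic
generator is included for tests and demos; only the primary SOC of each PT
is modelled (no multi-axiality, no HLT/HLGT/LLT levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .faers_io import normalize_pt

logger = logging.getLogger("faersig")

UNMAPPED = "UNMAPPED"

#: The 27 MedDRA system organ classes (spellings as printed in FAERS outputs).
MEDDRA_SOCS: tuple[str, ...] = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)


@dataclass
class PtSocMap:
    """A PT → primary-SOC lookup with a version tag."""

    entries: dict[str, str] = field(default_factory=dict)
    version_tag: str = ""

    def __post_init__(self) -> None:
        self.entries = {normalize_pt(k): v.strip() for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.entries


def resolve(pt: str, ptsoc: PtSocMap) -> str:
    """Resolve a preferred term to its primary SOC (total function).

    Unknown terms return :data:`UNMAPPED`; they still participate in
    PT-level screening but are dropped from SOC-level aggregation.
    """
    return ptsoc.entries.get(normalize_pt(pt), UNMAPPED)


def load_map(
    path: str | Path, delimiter: str = "\t", version_tag: str = ""
) -> PtSocMap:
    """Load a two-column (PT, SOC) delimited mapping file.

    Duplicate identical rows are collapsed; duplicate PT rows that disagree
    on the SOC are a hard error listing every offender.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 {delimiter!r}-separated columns")
            pt, soc = normalize_pt(parts[0]), parts[1].strip()
            if pt in entries and entries[pt] != soc:
                conflicts.append(f"{pt!r}: {entries[pt]!r} vs {soc!r} (line {lineno})")
            else:
                entries[pt] = soc
    if conflicts:
        raise ValueError(f"{path}: conflicting PT→SOC rows: " + "; ".join(conflicts))
    unknown_socs = {s for s in entries.values() if s not in MEDDRA_SOCS}
    if unknown_socs:
        logger.warning("%s: %d SOC names outside the 27-member list (toy ontology?)",
                       path, len(unknown_socs))
    return PtSocMap(entries=entries, version_tag=version_tag or path.name)


def write_map(ptsoc: PtSocMap, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for pt in sorted(ptsoc.entries):
            fh.write(f"{pt}{delimiter}{ptsoc.entries[pt]}\n")


# ---------------------------------------------------------------------------
# toy ontology (tests / demos / synthetic generator)
# ---------------------------------------------------------------------------

#: PT → primary SOC pairs for the generator's vocabulary: lower-urinary-tract
#: and cardiovascular terms typical of an overactive-bladder drug's safety
#: profile, plus a few terms from the conventionally excluded SOCs.
TOY_PT_SOC: tuple[tuple[str, str], ...] = (
    ("Cystitis", "Infections and infestations"),
    ("Pyelonephritis acute", "Infections and infestations"),
    ("Rhinitis", "Infections and infestations"),
    ("Kidney infection", "Infections and infestations"),
    ("Nasopharyngitis", "Infections and infestations"),
    ("Blood pressure increased", "Investigations"),
    ("Electrocardiogram qt prolonged", "Investigations"),
    ("Heart rate irregular", "Investigations"),
    ("Blood pressure systolic increased", "Investigations"),
    ("Intraocular pressure increased", "Investigations"),
    ("Blood urine present", "Investigations"),
    ("Antineutrophil cytoplasmic antibody increased", "Investigations"),
    ("Blood pressure abnormal", "Investigations"),
    ("Dementia", "Nervous system disorders"),
    ("Transient ischaemic attack", "Nervous system disorders"),
    ("Parkinson's disease", "Nervous system disorders"),
    ("Head discomfort", "Nervous system disorders"),
    ("Myasthenia gravis", "Nervous system disorders"),
    ("Headache", "Nervous system disorders"),
    ("Dizziness", "Nervous system disorders"),
    ("Muscle tightness", "Musculoskeletal and connective tissue disorders"),
    ("Muscle atrophy", "Musculoskeletal and connective tissue disorders"),
    ("Dry throat", "Respiratory, thoracic and mediastinal disorders"),
    ("Hyperventilation", "Respiratory, thoracic and mediastinal disorders"),
    ("Hallucination, visual", "Psychiatric disorders"),
    ("Abnormal dreams", "Psychiatric disorders"),
    ("Apathy", "Psychiatric disorders"),
    ("Eating disorder", "Psychiatric disorders"),
    ("Delirium", "Psychiatric disorders"),
    ("Anti-neutrophil cytoplasmic antibody positive vasculitis", "Immune system disorders"),
    ("Petechiae", "Skin and subcutaneous tissue disorders"),
    ("Angioedema", "Skin and subcutaneous tissue disorders"),
    ("Generalised oedema", "General disorders and administration site conditions"),
    ("Thirst", "General disorders and administration site conditions"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Urinary retention", "Renal and urinary disorders"),
    ("Dysuria", "Renal and urinary disorders"),
    ("Nocturia", "Renal and urinary disorders"),
    ("Urinary incontinence", "Renal and urinary disorders"),
    ("Pollakiuria", "Renal and urinary disorders"),
    ("Haematuria", "Renal and urinary disorders"),
    ("Micturition urgency", "Renal and urinary disorders"),
    ("Bladder pain", "Renal and urinary disorders"),
    ("Hypertonic bladder", "Renal and urinary disorders"),
    ("Urine flow decreased", "Renal and urinary disorders"),
    ("Postrenal failure", "Renal and urinary disorders"),
    ("Cystitis interstitial", "Renal and urinary disorders"),
    ("Cystitis haemorrhagic", "Renal and urinary disorders"),
    ("Hydronephrosis", "Renal and urinary disorders"),
    ("Bladder spasm", "Renal and urinary disorders"),
    ("Neurogenic bladder", "Renal and urinary disorders"),
    ("Urge incontinence", "Renal and urinary disorders"),
    ("Incontinence", "Renal and urinary disorders"),
    ("Erectile dysfunction", "Reproductive system and breast disorders"),
    ("Benign prostatic hyperplasia", "Reproductive system and breast disorders"),
    ("Vulvovaginal discomfort", "Reproductive system and breast disorders"),
    ("Dry mouth", "Gastrointestinal disorders"),
    ("Lip swelling", "Gastrointestinal disorders"),
    ("Swollen tongue", "Gastrointestinal disorders"),
    ("Mouth swelling", "Gastrointestinal disorders"),
    ("Peptic ulcer", "Gastrointestinal disorders"),
    ("Bowel movement irregularity", "Gastrointestinal disorders"),
    ("Colitis ischaemic", "Gastrointestinal disorders"),
    ("Constipation", "Gastrointestinal disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Atrial fibrillation", "Cardiac disorders"),
    ("Arrhythmia", "Cardiac disorders"),
    ("Palpitations", "Cardiac disorders"),
    ("Tachycardia", "Cardiac disorders"),
    ("Angina pectoris", "Cardiac disorders"),
    ("Extrasystoles", "Cardiac disorders"),
    ("Atrial flutter", "Cardiac disorders"),
    ("Ventricular extrasystoles", "Cardiac disorders"),
    ("Sinus node dysfunction", "Cardiac disorders"),
    ("Cardiac fibrillation", "Cardiac disorders"),
    ("Cardiac discomfort", "Cardiac disorders"),
    ("Atrial tachycardia", "Cardiac disorders"),
    ("Acute myocardial infarction", "Cardiac disorders"),
    ("Hypertension", "Vascular disorders"),
    ("Hypertensive crisis", "Vascular disorders"),
    ("Vasculitis", "Vascular disorders"),
    ("Malignant hypertension", "Vascular disorders"),
    ("Accelerated hypertension", "Vascular disorders"),
    ("Essential hypertension", "Vascular disorders"),
    ("Dry eye", "Eye disorders"),
    ("Eyelid oedema", "Eye disorders"),
    ("Glaucoma", "Eye disorders"),
    ("Retinal vein occlusion", "Eye disorders"),
    ("Vision blurred", "Eye disorders"),
    ("Visual impairment", "Eye disorders"),
    ("Hyperglycaemia", "Metabolism and nutrition disorders"),
    # terms in the SOCs conventionally excluded from drug-AE screening
    ("Fall", "Injury, poisoning and procedural complications"),
    ("Overdose", "Injury, poisoning and procedural complications"),
    ("Product quality issue", "Product issues"),
    ("Device malfunction", "Product issues"),
    ("Catheter placement", "Surgical and medical procedures"),
    ("Alcohol use", "Social circumstances"),
)


def toy_map() -> PtSocMap:
    """The bundled toy PT→SOC ontology (for tests, demos, synthetic data)."""
    return PtSocMap(entries=dict(TOY_PT_SOC), version_tag="toy-ontology")
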