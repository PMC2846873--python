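"""Static ICD-9-CM chapter/section lookup by code range.

The hierarchy ships as data: chapters partition the whole code space
(001-999, V01-V91, E000-E999) and sections are sub-ranges nested inside a
single chapter.  Codes are matched on their three-character rubric
(e.g. ``"250.00"`` -> ``250``, ``"V30.00"`` -> ``V30``); the part after the
decimal point never affects chapter or section membership.
"""

from __future__ import annotations

import re

from .errors import ParameterError

# (low, high, label) over numeric rubrics 001..999, plus V and E blocks.
CHAPTERS: list[tuple[str, int, int, str]] = [
    ("N", 1, 139, "Infectious and parasitic diseases"),
    ("N", 140, 239, "Neoplasms"),
    ("N", 240, 279,
     "Endocrine, nutritional and metabolic diseases, and immunity disorders"),
    ("N", 280, 289, "Diseases of the blood and blood-forming organs"),
    ("N", 290, 319, "Mental disorders"),
    ("N", 320, 389, "Diseases of the nervous system and sense organs"),
    ("N", 390, 459, "Diseases of the circulatory system"),
    ("N", 460, 519, "Diseases of the respiratory system"),
    ("N", 520, 579, "Diseases of the digestive system"),
    ("N", 580, 629, "Diseases of the genitourinary system"),
    ("N", 630, 679, "Complications of pregnancy, childbirth, and the puerperium"),
    ("N", 680, 709, "Diseases of the skin and subcutaneous tissue"),
    ("N", 710, 739, "Diseases of the musculoskeletal system and connective tissue"),
    ("N", 740, 759, "Congenital anomalies"),
    ("N", 760, 779, "Certain conditions originating in the perinatal period"),
    ("N", 780, 799, "Symptoms, signs, and ill-defined conditions"),
    ("N", 800, 999, "Injury and poisoning"),
    ("V", 1, 91,
     "Supplementary classification of factors influencing health status "
     "and contact with health services"),
    ("E", 0, 999,
     "Supplementary classification of external causes of injury and poisoning"),
]

SECTIONS: list[tuple[str, int, int, str]] = [
    # Infectious and parasitic diseases
    ("N", 1, 9, "Intestinal infectious diseases"),
    ("N", 10, 18, "Tuberculosis"),
    ("N", 20, 27, "Zoonotic bacterial diseases"),
    ("N", 30, 41, "Other bacterial diseases"),
    ("N", 42, 44, "Human immunodeficiency virus infection"),
    ("N", 45, 49,
     "Poliomyelitis and other non-arthropod-borne viral diseases of the "
     "central nervous system"),
    ("N", 50, 59, "Viral diseases accompanied by exanthem"),
    ("N", 60, 66, "Arthropod-borne viral diseases"),
    ("N", 70, 79, "Other diseases due to viruses and chlamydiae"),
    ("N", 80, 88, "Rickettsioses and other arthropod-borne diseases"),
    ("N", 90, 99, "Syphilis and other venereal diseases"),
    ("N", 100, 104, "Other spirochetal diseases"),
    ("N", 110, 118, "Mycoses"),
    ("N", 120, 129, "Helminthiases"),
    ("N", 130, 136, "Other infectious and parasitic diseases"),
    ("N", 137, 139, "Late effects of infectious and parasitic diseases"),
    # Neoplasms
    ("N", 140, 149, "Malignant neoplasm of lip, oral cavity, and pharynx"),
    ("N", 150, 159, "Malignant neoplasm of digestive organs and peritoneum"),
    ("N", 160, 165,
     "Malignant neoplasm of respiratory and intrathoracic organs"),
    ("N", 170, 176,
     "Malignant neoplasm of bone, connective tissue, skin, and breast"),
    ("N", 179, 189, "Malignant neoplasm of genitourinary organs"),
    ("N", 190, 199, "Malignant neoplasm of other and unspecified sites"),
    ("N", 200, 208,
     "Malignant neoplasm of lymphatic and haematopoietic tissue"),
    ("N", 209, 209, "Neuroendocrine tumors"),
    ("N", 210, 229, "Benign neoplasms"),
    ("N", 230, 234, "Carcinoma in situ"),
    ("N", 235, 238, "Neoplasms of uncertain behavior"),
    ("N", 239, 239, "Neoplasms of unspecified nature"),
    # Endocrine, nutritional, metabolic, immunity
    ("N", 240, 246, "Disorders of thyroid gland"),
    ("N", 249, 259, "Diseases of other endocrine glands"),
    ("N", 260, 269, "Nutritional deficiencies"),
    ("N", 270, 279, "Other metabolic disorders and immunity disorders"),
    # Blood
    ("N", 280, 289, "Diseases of the blood and blood-forming organs"),
    # Mental disorders
    ("N", 290, 294, "Organic psychotic conditions"),
    ("N", 295, 299, "Other psychoses"),
    ("N", 300, 316,
     "Neurotic disorders, personality disorders, and other nonpsychotic "
     "mental disorders"),
    ("N", 317, 319, "Intellectual disabilities"),
    # Nervous system and sense organs
    ("N", 320, 327,
     "Inflammatory and other diseases of the central nervous system"),
    ("N", 330, 337,
     "Hereditary and degenerative diseases of the central nervous system"),
    ("N", 338, 339, "Pain and other headache syndromes"),
    ("N", 340, 349, "Other disorders of the central nervous system"),
    ("N", 350, 359, "Disorders of the peripheral nervous system"),
    ("N", 360, 379, "Disorders of the eye and adnexa"),
    ("N", 380, 389, "Diseases of the ear and mastoid process"),
    # Circulatory
    ("N", 390, 392, "Acute rheumatic fever"),
    ("N", 393, 398, "Chronic rheumatic heart disease"),
    ("N", 401, 405, "Hypertensive disease"),
    ("N", 410, 414, "Ischaemic heart disease"),
    ("N", 415, 417, "Diseases of pulmonary circulation"),
    ("N", 420, 429, "Other forms of heart disease"),
    ("N", 430, 438, "Cerebrovascular disease"),
    ("N", 440, 449, "Diseases of arteries, arterioles, and capillaries"),
    ("N", 451, 459,
     "Diseases of veins and lymphatics, and other diseases of circulatory "
     "system"),
    # Respiratory
    ("N", 460, 466, "Acute respiratory infections"),
    ("N", 470, 478, "Other diseases of the upper respiratory tract"),
    ("N", 480, 488, "Pneumonia and influenza"),
    ("N", 490, 496,
     "Chronic obstructive pulmonary disease and allied conditions"),
    ("N", 500, 508,
     "Pneumoconioses and other lung diseases due to external agents"),
    ("N", 510, 519, "Other diseases of respiratory system"),
    # Digestive
    ("N", 520, 529,
     "Diseases of oral cavity, salivary glands, and jaws"),
    ("N", 530, 539, "Diseases of esophagus, stomach, and duodenum"),
    ("N", 540, 543, "Appendicitis"),
    ("N", 550, 553, "Hernia of abdominal cavity"),
    ("N", 555, 558, "Noninfectious enteritis and colitis"),
    ("N", 560, 569, "Other diseases of intestines and peritoneum"),
    ("N", 570, 579, "Other diseases of digestive system"),
    # Genitourinary
    ("N", 580, 589, "Nephritis, nephrotic syndrome, and nephrosis"),
    ("N", 590, 599, "Other diseases of urinary system"),
    ("N", 600, 608, "Diseases of male genital organs"),
    ("N", 610, 612, "Disorders of breast"),
    ("N", 614, 616, "Inflammatory disease of female pelvic organs"),
    ("N", 617, 629, "Other disorders of female genital tract"),
    # Pregnancy, childbirth, puerperium
    ("N", 630, 639, "Ectopic and molar pregnancy and abortive outcome"),
    ("N", 640, 649, "Complications mainly related to pregnancy"),
    ("N", 650, 659,
     "Normal delivery, and other indications for care in pregnancy, labor, "
     "and delivery"),
    ("N", 660, 669,
     "Complications occurring mainly in the course of labor and delivery"),
    ("N", 670, 677, "Complications of the puerperium"),
    ("N", 678, 679, "Other maternal and fetal complications"),
    # Skin
    ("N", 680, 686, "Infections of skin and subcutaneous tissue"),
    ("N", 690, 698, "Other inflammatory conditions of skin"),
    ("N", 700, 709, "Other diseases of skin and subcutaneous tissue"),
    # Musculoskeletal
    ("N", 710, 719, "Arthropathies and related disorders"),
    ("N", 720, 724, "Dorsopathies"),
    ("N", 725, 729, "Rheumatism, excluding the back"),
    ("N", 730, 739,
     "Osteopathies, chondropathies, and acquired musculoskeletal deformities"),
    # Congenital anomalies
    ("N", 740, 759, "Congenital anomalies"),
    # Perinatal
    ("N", 760, 763,
     "Maternal causes of perinatal morbidity and mortality"),
    ("N", 764, 779,
     "Other conditions originating in the perinatal period"),
    # Symptoms, signs
    ("N", 780, 789, "Symptoms"),
    ("N", 790, 796, "Nonspecific abnormal findings"),
    ("N", 797, 799,
     "Ill-defined and unknown causes of morbidity and mortality"),
    # Injury and poisoning
    ("N", 800, 804, "Fracture of skull"),
    ("N", 805, 809, "Fracture of neck and trunk"),
    ("N", 810, 819, "Fracture of upper limb"),
    ("N", 820, 829, "Fracture of lower limb"),
    ("N", 830, 839, "Dislocation"),
    ("N", 840, 848, "Sprains and strains of joints and adjacent muscles"),
    ("N", 850, 854, "Intracranial injury, excluding those with skull fracture"),
    ("N", 860, 869, "Internal injury of thorax, abdomen, and pelvis"),
    ("N", 870, 879, "Open wound of head, neck, and trunk"),
    ("N", 880, 887, "Open wound of upper limb"),
    ("N", 890, 897, "Open wound of lower limb"),
    ("N", 900, 904, "Injury to blood vessels"),
    ("N", 905, 909,
     "Late effects of injuries, poisonings, toxic effects, and other "
     "external causes"),
    ("N", 910, 919, "Superficial injury"),
    ("N", 920, 924, "Contusion with intact skin surface"),
    ("N", 925, 929, "Crushing injury"),
    ("N", 930, 939, "Effects of foreign body entering through orifice"),
    ("N", 940, 949, "Burns"),
    ("N", 950, 957, "Injury to nerves and spinal cord"),
    ("N", 958, 959,
     "Certain traumatic complications and unspecified injuries"),
    ("N", 960, 979, "Poisoning by drugs, medicinals and biological substances"),
    ("N", 980, 989,
     "Toxic effects of substances chiefly nonmedicinal as to source"),
    ("N", 990, 995, "Other and unspecified effects of external causes"),
    ("N", 996, 999,
     "Complications of surgical and medical care, not elsewhere classified"),
    # V codes
    ("V", 1, 9,
     "Persons with potential health hazards related to communicable diseases"),
    ("V", 10, 19,
     "Persons with potential health hazards related to personal and family "
     "history"),
    ("V", 20, 29,
     "Persons encountering health services in circumstances related to "
     "reproduction and development"),
    ("V", 30, 39, "Liveborn infants according to type of birth"),
    ("V", 40, 49,
     "Persons with a condition influencing their health status"),
    ("V", 50, 59,
     "Persons encountering health services for specific procedures and "
     "aftercare"),
    ("V", 60, 69,
     "Persons encountering health services in other circumstances"),
    ("V", 70, 82,
     "Persons without reported diagnosis encountered during examination and "
     "investigation"),
    ("V", 83, 84, "Genetics"),
    ("V", 85, 91, "Other supplementary classification codes"),
    # E codes (coarse blocks; totality at chapter level only)
    ("E", 0, 30, "External cause status and activity"),
    ("E", 800, 848, "Transport accidents"),
    ("E", 849, 849, "Place of occurrence"),
    ("E", 850, 858, "Accidental poisoning by drugs and biologicals"),
    ("E", 860, 869,
     "Accidental poisoning by other solid and liquid substances, gases, and "
     "vapors"),
    ("E", 870, 879,
     "Misadventures and abnormal reactions during medical care"),
    ("E", 880, 888, "Accidental falls"),
    ("E", 890, 899, "Accidents caused by fire and flames"),
    ("E", 900, 909, "Accidents due to natural and environmental factors"),
    ("E", 910, 915, "Accidents caused by submersion, suffocation, and foreign bodies"),
    ("E", 916, 928, "Other accidents"),
    ("E", 929, 929, "Late effects of accidental injury"),
    ("E", 930, 949,
     "Drugs, medicinal and biological substances causing adverse effects in "
     "therapeutic use"),
    ("E", 950, 959, "Suicide and self-inflicted injury"),
    ("E", 960, 969, "Homicide and injury purposely inflicted by other persons"),
    ("E", 970, 979, "Legal intervention"),
    ("E", 980, 989,
     "Injury undetermined whether accidentally or purposely inflicted"),
    ("E", 990, 999, "Injury resulting from operations of war"),
]

_CODE_RE = re.compile(r"^(?P<prefix>[VEve]?)(?P<num>\d{1,3})(?:\.\d{1,2})?$")


def parse_rubric(code: str) -> tuple[str, int]:
    """Split an ICD-9-CM code into its (block, numeric rubric) pair.

    ``block`` is ``"N"`` for plain numeric codes, ``"V"`` or ``"E"`` for
    the supplementary classifications.
    """
    if not isinstance(code, str):
        raise ParameterError(f"code: expected string, got {type(code).__name__}")
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ParameterError(f"code: {code!r} is not a valid ICD-9-CM code")
    prefix = m.group("prefix").upper() or "N"
    num = int(m.group("num"))
    if prefix == "N" and num == 0:
        raise ParameterError(f"code: {code!r} is not a valid ICD-9-CM code")
    if prefix == "V" and not 1 <= num <= 91:
        raise ParameterError(f"code: {code!r} outside the V01-V91 block")
    return prefix, num


def _scan(table, prefix, num):
    for block, low, high, label in table:
        if block == prefix and low <= num <= high:
            return label
    return None


def chapter_of(code: str) -> str:
    """Return the chapter label for a code; total over all valid codes."""
    prefix, num = parse_rubric(code)
    label = _scan(CHAPTERS, prefix, num)
    if label is None:  # unreachable for valid codes; chapters partition space
        raise ParameterError(f"code: {code!r} maps to no ICD-9-CM chapter")
    return label


def section_of(code: str) -> str | None:
    """Return the section label for a code, or None for unassigned rubrics."""
    prefix, num = parse_rubric(code)
    return _scan(SECTIONS, prefix, num)
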