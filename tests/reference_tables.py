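"""Published per-breed diversity values from a bovine SNP-array study.

Observed heterozygosity (Ho) and inbreeding coefficient (F) for 37 cattle
populations — European and African taurine, Sanga, indicine, Asian local,
one feral population and wild Bos species — computed on an
outgroup-polymorphic (ancestral) SNP panel.  Used to validate the
inbreeding estimator: if F was referenced to a common pooled expected
heterozygosity He, then Ho/(1-F) must be (nearly) the same number for
every breed, from Angus to gaur, despite Ho itself varying three-fold.

Columns: acronym, type, n individuals, Ho, F.
"""

REFERENCE_DIVERSITY = [
    ("ANG", "European taurus", 24, 0.314, 0.21),
    ("HFD", "European taurus", 24, 0.305, 0.24),
    ("BSW", "European taurus", 24, 0.309, 0.23),
    ("FLV", "European taurus", 24, 0.328, 0.18),
    ("HOL", "European taurus", 24, 0.332, 0.17),
    ("LMS", "European taurus", 24, 0.330, 0.17),
    ("PIE", "European taurus", 24, 0.345, 0.14),
    ("ROM", "European taurus", 24, 0.321, 0.20),
    ("MCG", "European taurus", 13, 0.329, 0.18),
    ("CHI", "European taurus", 16, 0.316, 0.21),
    ("MUT", "African taurus", 13, 0.227, 0.43),
    ("NDA", "African taurus", 23, 0.283, 0.29),
    ("NGA", "Sanga", 24, 0.342, 0.14),
    ("ANW", "Sanga", 24, 0.322, 0.19),
    ("GIR", "Indicus", 24, 0.260, 0.35),
    ("THA", "Indicus", 13, 0.227, 0.43),
    ("LOH", "Indicus", 13, 0.252, 0.37),
    ("NYP", "Indicus", 24, 0.264, 0.34),
    ("YAB", "Asian local N", 24, 0.323, 0.19),
    ("LHS", "Asian local N", 14, 0.370, 0.07),
    ("LIZ", "Asian local N", 19, 0.358, 0.10),
    ("QIC", "Asian local N", 24, 0.365, 0.08),
    ("JIN", "Asian local N", 14, 0.363, 0.09),
    ("ACE", "Asian local S", 12, 0.263, 0.34),
    ("BNA", "Asian local S", 14, 0.301, 0.25),
    ("DEH", "Asian local S", 16, 0.273, 0.32),
    ("HOH", "Asian local S", 12, 0.355, 0.11),
    ("DEC", "Asian local S", 24, 0.338, 0.15),
    ("LUX", "Asian local S", 11, 0.363, 0.09),
    ("NAY", "Asian local S", 23, 0.357, 0.11),
    ("ENS", "Asian local S", 24, 0.340, 0.15),
    ("WAN", "Asian local S", 24, 0.319, 0.20),
    ("WEL", "Asian local S", 24, 0.295, 0.26),
    ("HKF", "Feral", 21, 0.268, 0.35),
    ("OGA", "Semi-Wild", 21, 0.183, 0.54),
    ("BAN", "Wild", 14, 0.132, 0.67),
    ("GAU", "Wild", 10, 0.112, 0.72),
]
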