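"""Built-in class summary statistics for the six citrus peel classes.

Each entry is ``(mean, sd)`` in the units noted per block.  FTIR bands that
were not detected in a class are recorded as ``None`` and treated downstream
as zero intensity (not missing data).  These tables parameterize the
synthetic-data generator and the class-mean correlation analysis.
"""

from __future__ import annotations

#: Canonical class order used everywhere (rows of every generated block).
CLASS_LABELS = (
    "yellow_grapefruit",
    "red_grapefruit",
    "lemon",
    "orange",
    "clementine",
    "kumquat",
)

#: Physicochemical block: moisture of the fresh peel (%), ascorbic acid
#: (mg/100 g DW), total soluble solids (degrees Brix).
PHYSICO_FEATURES = ("moisture", "ascorbic_acid", "tss_brix")

PHYSICO = {
    "yellow_grapefruit": {"moisture": (67.76, 4.00), "ascorbic_acid": (114.12, 12.71), "tss_brix": (10.73, 0.90)},
    "red_grapefruit":    {"moisture": (69.85, 4.21), "ascorbic_acid": (104.54, 12.54), "tss_brix": (10.30, 1.34)},
    "lemon":             {"moisture": (68.36, 5.66), "ascorbic_acid": (56.78, 12.64), "tss_brix": (10.00, 1.70)},
    "orange":            {"moisture": (63.92, 5.61), "ascorbic_acid": (65.13, 12.69), "tss_brix": (15.55, 1.44)},
    "clementine":        {"moisture": (69.82, 5.62), "ascorbic_acid": (56.89, 12.67), "tss_brix": (10.80, 1.69)},
    "kumquat":           {"moisture": (74.95, 3.53), "ascorbic_acid": (65.01, 5.07), "tss_brix": (17.43, 2.38)},
}

#: Spectrophotometric block: total phenolic content (mg GAE/g DW), total
#: flavonoid content (mg QE/g DW), FRAP (mg Fe(II)/g DW, "antioxidant
#: activity"), ABTS radical scavenging (mg Trolox/g DW, "antiradical
#: activity").
SPECTRO_FEATURES = ("tpc", "tfc", "frap", "abts")

SPECTRO = {
    "yellow_grapefruit": {"tpc": (18.21, 0.56), "tfc": (27.01, 2.00), "frap": (31.82, 2.16), "abts": (19.92, 1.37)},
    "red_grapefruit":    {"tpc": (17.42, 0.83), "tfc": (24.30, 1.83), "frap": (30.32, 1.45), "abts": (14.26, 0.65)},
    "lemon":             {"tpc": (14.29, 1.27), "tfc": (31.90, 2.16), "frap": (42.10, 2.12), "abts": (18.66, 0.86)},
    "orange":            {"tpc": (13.62, 1.05), "tfc": (24.16, 2.13), "frap": (34.84, 3.44), "abts": (16.13, 1.15)},
    "clementine":        {"tpc": (9.90, 0.72), "tfc": (13.91, 1.07), "frap": (39.50, 2.62), "abts": (15.39, 1.12)},
    "kumquat":           {"tpc": (4.86, 0.53), "tfc": (7.63, 0.98), "frap": (13.16, 0.98), "abts": (6.71, 0.40)},
}

#: ATR-FTIR band-intensity block over 4000-499 cm-1.  One row per band region
#: (labels in cm-1, descending); per-class (mean, sd) absorbance or None when
#: the band is absent in that class.  Column order inside each tuple follows
#: CLASS ORDER of the keys below, not CLASS_LABELS.
FTIR_CLASS_ORDER = ("orange", "lemon", "red_grapefruit", "yellow_grapefruit", "clementine", "kumquat")

FTIR_BANDS = {
    "3630":      (None, (0.010, 0.002), None, None, None, None),
    "3525":      (None, None, None, None, (0.017, 0.003), None),
    "3414":      (None, None, None, None, (0.030, 0.006), None),
    "3300":      ((0.789, 0.005), (0.049, 0.005), (0.052, 0.004), (0.071, 0.005), (0.022, 0.003), (0.810, 0.019)),
    "3078":      (None, (0.064, 0.006), None, (0.031, 0.001), None, None),
    "3010":      (None, (0.016, 0.003), (0.021, 0.001), (0.023, 0.002), None, None),
    "2962":      (None, (0.126, 0.015), (0.077, 0.005), (0.092, 0.004), None, None),
    "2922":      ((0.255, 0.024), (0.483, 0.022), (0.414, 0.031), (0.388, 0.018), (0.299, 0.016), (0.168, 0.005)),
    "2850":      ((0.085, 0.002), None, (0.104, 0.001), (0.034, 0.004), (0.108, 0.010), None),
    "1730":      ((0.046, 0.006), (0.116, 0.006), (0.160, 0.019), (0.149, 0.011), (0.094, 0.007), (0.119, 0.014)),
    "1643":      (None, (0.046, 0.005), (0.076, 0.003), (0.055, 0.004), (0.298, 0.011), (0.118, 0.011)),
    "1600":      ((0.237, 0.022), (0.255, 0.024), (0.199, 0.017), (0.141, 0.007), (0.283, 0.008), None),
    "1517":      ((0.024, 0.002), (0.076, 0.005), (0.018, 0.003), (0.023, 0.004), (0.211, 0.007), (0.023, 0.003)),
    "1439":      (None, (0.228, 0.022), (0.200, 0.023), (0.200, 0.021), (0.088, 0.008), None),
    "1400":      ((0.064, 0.004), None, None, None, (0.028, 0.002), (0.049, 0.002)),
    "1370-1360": ((0.023, 0.003), (0.093, 0.007), (0.064, 0.004), (0.064, 0.005), (0.051, 0.003), (0.032, 0.003)),
    "1330":      (None, (0.013, 0.001), None, (0.018, 0.002), None, None),
    "1300":      (None, None, None, None, (0.050, 0.005), None),
    "1280-1274": (None, (0.049, 0.003), None, None, (0.137, 0.004), None),
    "1240":      ((0.045, 0.003), (0.064, 0.003), (0.082, 0.003), (0.105, 0.004), (0.078, 0.007), (0.040, 0.004)),
    "1200":      (None, (0.052, 0.002), None, None, (0.087, 0.006), None),
    "1182":      (None, None, None, None, (0.061, 0.002), None),
    "1147":      (None, (0.055, 0.008), None, None, (0.109, 0.006), None),
    "1093":      (None, (0.081, 0.009), None, None, (0.123, 0.005), (0.034, 0.004)),
    "1055":      (None, (0.044, 0.003), None, (0.062, 0.005), (0.096, 0.010), None),
    "1016-1012": ((0.545, 0.042), (0.538, 0.021), (0.636, 0.026), (0.610, 0.039), (0.228, 0.009), (0.117, 0.009)),
    "975":       (None, (0.053, 0.003), None, None, (0.142, 0.005), (0.077, 0.005)),
    "920":       ((0.019, 0.002), (0.018, 0.002), (0.021, 0.002), (0.020, 0.005), (0.015, 0.002), (0.051, 0.004)),
    "890":       ((0.016, 0.003), (0.188, 0.016), (0.126, 0.010), (0.149, 0.031), None, (0.016, 0.002)),
    "842":       (None, None, None, None, (0.035, 0.001), None),
    "812":       ((0.017, 0.002), (0.024, 0.002), (0.024, 0.002), (0.018, 0.003), (0.102, 0.003), (0.021, 0.002)),
    "765":       ((0.024, 0.004), (0.014, 0.001), (0.014, 0.001), (0.022, 0.003), (0.077, 0.004), (0.018, 0.002)),
    "738":       (None, None, None, None, (0.061, 0.004), None),
    "669":       (None, None, None, None, (0.015, 0.001), None),
    "623":       ((0.012, 0.001), None, None, (0.015, 0.002), (0.051, 0.002), None),
    "586":       ((0.008, 0.002), (0.018, 0.002), (0.007, 0.001), (0.008, 0.001), (0.035, 0.005), (0.011, 0.001)),
    "530-524":   ((0.016, 0.003), (0.029, 0.004), (0.009, 0.001), (0.024, 0.003), (0.032, 0.005), (0.009, 0.002)),
}

#: Optional chemical annotation strings per band region (vibration modes and
#: compound classes), carried as opaque display metadata.
BAND_ANNOTATIONS = {
    "3630": "nu(OH) - pectin, phenolic compounds",
    "3525": "nu(OH) - pectin, phenolic compounds",
    "3414": "nu(OH) - pectin, phenolic compounds",
    "3300": "nu(OH) - water, carbohydrates, organic acids, polyphenols",
    "2962": "nu(C(sp3)-H) - carbohydrates, carboxylic acids, flavonoid glycosides",
    "2922": "nu(C(sp3)-H) - carbohydrates, carboxylic acids, flavonoid glycosides",
    "2850": "nu(C(sp3)-H) - carbohydrates, carboxylic acids, flavonoid glycosides",
    "1730": "nu(C=O) - organic acids, esters, cutin",
    "1643": "delta(OH)/nu(C=O) - polyphenols, carbohydrates, flavonoids",
    "1600": "nu(C-C)/nu(COOH) - pectin, aromatic compounds",
    "1517": "nu(C=C-C) aromatic - phenolic compounds",
    "1439": "delta(C-H)/delta(O-H)/nu(COOH) - carbohydrates (pectin)",
    "1400": "delta(C-H)/delta(O-H)/nu(COOH) - carbohydrates (pectin)",
    "1370-1360": "nu(CH3)/nu(C-OOH) - organic acids, carbohydrates",
    "1330": "delta(C-H) - polysaccharides (cellulose)",
    "1300": "delta(C-H) - polysaccharides (cellulose)",
    "1280-1274": "delta(O-H)/amide III - cutin, polysaccharides, proteins",
    "1240": "nu(C-O)/nu(C=C) - polyphenols, carbohydrates",
    "1200": "nu(C-O-C) - cellulose",
    "1182": "nu(C-O-C)/nu(C-C) - cellulose",
    "1147": "nu(C-O-C) - cutin, pectin, cellulose",
    "1093": "nu(C-O)/nu(C-C) - pectin, polysaccharides",
    "1055": "delta(C-O)/nu(C-OH) - carbohydrates (cellulose, sucrose)",
    "1016-1012": "nu(C-O)/nu(C-C)/delta(C-OH) - pectin, cellulose",
    "975": "delta(trans C-H) - carotenoids",
    "920": "delta(C=C)/delta(C-H) - alkenes, phenol benzene ring",
    "890": "delta(C-H) - para-substituted aromatic rings",
    "842": "delta(C-H) - para-substituted aromatic rings",
    "812": "C-H - aromatic ring of phenols",
    "765": "delta(OH)/delta(C-H) - C-OH group, ortho-substituted aromatics",
    "738": "delta(cis C-H) - carotenoids",
    "669": "delta(O-H) - pectin",
    "623": "delta(O-H) - pectin",
    "586": "delta(C-H) - polyphenols and flavonoids",
    "530-524": "delta(C-O-C) - glycosidic bond of pectin",
}
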