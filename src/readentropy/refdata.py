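"""Published validation measurements for 20 BAC insert sequences.

Each tuple is (accession, length_bp, H30, I30, dH30_percent): the
published 30-mer entropy H^30, maximum entropy I^30 and relative
entropy loss for BAC inserts from Arabidopsis thaliana and Drosophila
melanogaster whose de novo assembly behaviour is well characterized.
These serve as numeric cross-checks of the entropy formulas:

* I^30 equals log10(2*(L - 29)) to ~1e-5 (the tiny deficit comes from a
  handful of ambiguity-containing windows excluded from counting);
* the printed dH^30 percentage equals (I - H)/I to 2 decimal places.

The three high-loss inserts (AC018460, AC018485, AC018482) are exactly
the ones reported to assemble poorly from 30 bp reads, which anchors
the >1% loss rule of thumb.
"""

from __future__ import annotations

BAC_VALIDATION: tuple[tuple[str, int, float, float, float], ...] = (
    ("AC011809", 108767, 5.335862, 5.337411, 0.03),
    ("AC002328", 109171, 5.335947, 5.339022, 0.06),
    ("AC064879", 109180, 5.335971, 5.339058, 0.06),
    ("AC023673", 109367, 5.338616, 5.339801, 0.02),
    ("AC011713", 109694, 5.332009, 5.341098, 0.17),
    ("AC009243", 110565, 5.344373, 5.344534, 0.00),
    ("AC022520", 110611, 5.341812, 5.344714, 0.05),
    ("AC018460", 110619, 4.99782, 5.344746, 6.49),
    ("AC007764", 111222, 5.346664, 5.347107, 0.01),
    ("AC000348", 111566, 5.339937, 5.348449, 0.16),
    ("AC092191", 80919, 5.205896, 5.208925, 0.06),
    ("AC185533", 95808, 5.271617, 5.2823, 0.20),
    ("AC018485", 99441, 5.094117, 5.298469, 3.86),
    ("AC018478", 103809, 5.315052, 5.317144, 0.04),
    ("AC092242", 111023, 5.346276, 5.346329, 0.00),
    ("AC018482", 113821, 5.261927, 5.357142, 1.78),
    ("AC185534", 119461, 5.37266, 5.378151, 0.10),
    ("AC092399", 122013, 5.386815, 5.387333, 0.01),
    ("AC007837", 123647, 5.391958, 5.393112, 0.02),
    ("AC007329", 126140, 5.401638, 5.401783, 0.00),
)

BAC_READ_LENGTH = 30
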