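"""Published benchmark tallies used in worked examples and cross-checks.

These are the printed outcome tables of a published highbush blueberry
('Bluecrop') 454 EST survey: the per-assembly contig/singleton totals, the
microsatellite motif-composition counts, the 100-primer EST-SSR marker screen,
and the 17 genes whose read-predicted expression patterns were compared with
real-time PCR.  They are inputs — the package recomputes every derived
quantity (totals, percentages, rates, concordance) from them at run time.
"""

from __future__ import annotations

import pandas as pd

from .ssr import MarkerScreenRecord

#: Per-assembly read and unigene tallies (the "all samples" joint assembly
#: plus the three organ-level assemblies).
ASSEMBLY_TOTALS = pd.DataFrame(
    [
        ("all", 614028, 490517, 14764, 123511),
        ("bud", 291342, 228938, 10350, 62404),
        ("fruit", 259527, 199643, 6726, 59884),
        ("leaf", 62465, 36763, 1781, 25702),
    ],
    columns=["assembly", "reads_assembled", "reads_in_contigs",
             "n_contigs", "n_singletons"],
)

#: Unigenes >= 120 nt that entered SSR mining.
N_SEQUENCES_MINED = 87071

#: SSR counts by motif-length category (di-, tri-, tetra-, pentanucleotide).
SSR_CATEGORY_COUNTS = {"DNR": 7942, "TNR": 4120, "TetraNR": 2274, "PentaNR": 1550}

#: Canonical-class counts within the di- and trinucleotide categories.
SSR_DNR_CLASS_COUNTS = {"CG": 31, "AC": 530, "AT": 1347, "AG": 6034}
SSR_TNR_CLASS_COUNTS = {
    "AAC": 177, "AAG": 1310, "AAT": 305, "ACC": 600, "ACG": 159,
    "ACT": 246, "AGC": 426, "AGG": 424, "ATC": 327, "CCG": 146,
}

#: Read-predicted vs qPCR-observed expression patterns for the 17 genes the
#: survey examined (the two previously characterised cold-induced controls
#: shown alongside them are not part of the 17-gene comparison).  The pectate
#: lyase profile was counted as concordant.  Vocabulary matches the trend
#: classifier: up, down, up_down, down_up, flat, complex.
QPCR_TREND_PAIRS = pd.DataFrame(
    [
        # bud cold-acclimation series
        ("pyrophosphate-dependent phosphofructokinase", "bud", "down_up", "down_up"),
        ("arginine decarboxylase", "bud", "down_up", "down_up"),
        ("lipoxygenase", "bud", "down", "down"),
        ("abscisic stress ripening protein", "bud", "down_up", "down_up"),
        ("hypothetical protein", "bud", "down_up", "down_up"),
        ("lipid transfer protein", "bud", "up_down", "down_up"),
        ("amino acid selective channel protein", "bud", "up_down", "up_down"),
        ("pointed first leaf", "bud", "up", "up"),
        ("high mobility group protein", "bud", "up_down", "up_down"),
        # fruit ripening series
        ("pectate lyase", "fruit", "up_down", "up_down"),
        ("cysteine protease-like protein", "fruit", "up_down", "complex"),
        ("glutathione peroxidase", "fruit", "up_down", "up_down"),
        ("chalcone synthase", "fruit", "up_down", "up_down"),
        ("anthocyanidin synthase", "fruit", "up_down", "up_down"),
        ("aspartic proteinase", "fruit", "up", "flat"),
        ("1-aminocyclopropane-1-carboxylate oxidase", "fruit", "up", "up"),
        ("flavonoid 3-hydroxylase", "fruit", "up", "up"),
    ],
    columns=["gene", "group", "predicted", "observed"],
)


def marker_screen_records() -> list[MarkerScreenRecord]:
    """The 100-primer screen outcome: 32 primer pairs never amplified, one
    (VCB-C-13051) amplified only in the tetraploid accessions, 25 were
    monomorphic, and 43 polymorphic."""
    accessions = ("tetraploid", "diploid")
    records: list[MarkerScreenRecord] = []
    i = 0

    def _add(n, amplified, call):
        nonlocal i
        for _ in range(n):
            i += 1
            records.append(MarkerScreenRecord(
                primer_id=f"VCB-{i:03d}",
                amplified=dict(zip(accessions, amplified)),
                call=call,
            ))

    _add(32, (False, False), "no_product")
    _add(25, (True, True), "monomorphic")
    # VCB-C-13051: polymorphic, amplified only in the tetraploid population
    _add(1, (True, False), "polymorphic")
    _add(42, (True, True), "polymorphic")
    assert len(records) == 100
    return records
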