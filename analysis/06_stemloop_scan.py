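#!/usr/bin/env python
"""Scan model substrates for CNGNNGN stem-loops.

Scans two synthetic hairpins built in code: a consensus splice-site-like
hairpin with a 5-bp stem, and the unmodified anticodon arm of tRNA-Phe
(a synthetic stand-in assembled from the canonical anticodon-arm
pattern: 5-bp stem closing the CUGAAGA heptaloop). Both yield exactly
one hit with the cut 3' of loop position 3; adding the natural
2'-O-methyl mark on the anticodon G suppresses cleavability of the
tRNA hit.
"""

from pathlib import Path

from ire1_rnase import stemloop as sl

ROOT = Path(__file__).resolve().parents[1]

CONSENSUS_HP = "GCGGCCUGCAGCGCCGC"
TRNA_PHE_ASL = "CCAGACUGAAGAUCUGG"  # synthetic unmodified anticodon arm


def main() -> None:
    all_hits = []
    for seq_id, seq in (("consensus_hp", CONSENSUS_HP),
                        ("tRNA_Phe_ASL", TRNA_PHE_ASL)):
        hits = sl.find_stemloops(seq, sequence_id=seq_id)
        all_hits.extend(hits)
        for h in hits:
            print(f"{seq_id}: loop {h.loop_seq} at {h.loop_start}, "
                  f"{h.stem_len}-bp stem, cut after {h.cleavage_site} nt "
                  f"(scissile G at index {h.scissile_index})")

    out = ROOT / "results" / "stemloop_hits.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(sl.hits_to_table(all_hits))

    trna_hit = [h for h in all_hits if h.sequence_id == "tRNA_Phe_ASL"][0]
    unmod = sl.annotate_cleavage(trna_hit)
    modded = sl.annotate_cleavage(trna_hit, [trna_hit.scissile_index])
    print(f"unmodified anticodon loop cleavable: {unmod}")
    print(f"with 2'-O-methyl on the anticodon G: {modded}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
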