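"""Project a QTL from its study map onto the reference map.

Different studies use different linkage maps; meta-analysis needs every
QTL on one reference map.  Shared markers anchor a local affine rescaling:
position and CI endpoints are interpolated piecewise-linearly between the
tightest flanking markers present on both maps.
"""
import pandas as pd

from metaqtl import GeneticMap, QTLRecord, find_common_flank, project_qtl

study = GeneticMap("STUDY", {1: pd.DataFrame(
    [("umc11", 10.0), ("bnlg176", 30.0), ("phi095", 55.0)],
    columns=["marker", "pos_cM"])})
reference = GeneticMap("REF", {1: pd.DataFrame(
    [("umc11", 100.0), ("bnlg176", 140.0), ("phi095", 170.0), ("end", 400.0)],
    columns=["marker", "pos_cM"])})

qtl = QTLRecord(qtl_id="q1", study_id="S1", trait="ASI", chromosome=1,
                position=20.0, ci_start=15.0, ci_end=25.0, lod=4.0, pve=12.0,
                pop_type="RIL", pop_size=180, map_id="STUDY",
                trait_category="FR")

flank = find_common_flank(study, reference, 1, qtl.position)
print(f"anchor markers around {qtl.position} cM: {flank}")

p = project_qtl(qtl, study, reference)
print(f"study position {qtl.position:.1f} cM -> reference "
      f"{p.ref_position:.1f} cM")
print(f"study CI [{qtl.ci_start:.1f}, {qtl.ci_end:.1f}] -> reference "
      f"[{p.ref_ci_lo:.1f}, {p.ref_ci_hi:.1f}] (status: "
      f"{p.projection_status})")
# The 20 cM between the anchors maps onto 40 reference cM, so the local
# scale is 2x: the QTL lands at 120 cM with a 20 cM-wide reference CI.
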