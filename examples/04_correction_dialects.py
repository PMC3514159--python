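"""Recover the published correction multipliers from the packaged tables.

The published per-term GO statistics imply a test count m through the
ratio corrected/raw x rank, and the per-pathway table implies one Bonferroni
multiplier per source database.  Both are recovered here from the printed
numbers alone and used to reproduce two printed corrected values.
"""
import numpy as np

from y2hnet import CorrectionConfig, bonferroni, multiple_test_correct
from y2hnet.datasets import hoxa1_go_reference, hoxa1_pathway_reference
from y2hnet.direct import infer_test_count

go = hoxa1_go_reference().sort_values("p_value").reset_index(drop=True)
m = infer_test_count(go["p_value"][1:6], go["corr_p_value"][1:6],
                     ranks=range(2, 7))
corrected = multiple_test_correct(
    go["p_value"][:6].tolist(), CorrectionConfig(mode="paper_simple", m=m)
)
print(f"recovered GO test count m = {m}")
print(f"rank-1 corrected p: computed {corrected[0]:.6g}, "
      f"printed {go['corr_p_value'][0]:.6g}")

pw = hoxa1_pathway_reference()
for source in ("NCI-Nature", "KEGG", "Reactome"):
    sub = pw[pw["source"] == source]
    m_src = int(round(float(np.median(sub["corr_fdr"] / sub["fdr"]))))
    print(f"{source}: Bonferroni multiplier {m_src} "
          f"({len(sub)} printed pathways)")

focal = pw[pw["pathway_id"] == "hsa04510"].iloc[0]
print(f"Focal adhesion corrected FDR: computed "
      f"{bonferroni(focal['fdr'], 150):.4g}, printed {focal['corr_fdr']:.4g}")
# The multipliers differ per source because each database was corrected as
# its own family of tests.
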