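"""Score promoter windows by CpG density and classify CpG islands.

Loads the packaged synthetic CRP-like promoter (551 bp, the -550 ~ +1 bp
window) and simulates one CGI-like promoter for contrast, then prints the
observed/expected CpG ratio and classification of each.  The ratio is
n_CpG * L / (n_C * n_G); a promoter with ratio > 0.6 is a CpG island,
anything at or below is CpG-poor.  Acute-phase genes such as CRP sit near
0.23 — far below the island threshold — which is what leaves their
promoters open to regulatory methylation.
"""

from amplimeth import cpg, simulate
from amplimeth.datasets import load_crp_like_amplicon

amp = load_crp_like_amplicon()
density = cpg.cpg_obs_exp_ratio(amp.sequence)
print(f"{amp.name}: length={density.length}  n_CpG={density.n_cpg}  "
      f"ratio={density.ratio:.3f}  class={cpg.classify_cgi(density)}")

cgi_seq = simulate.simulate_promoter_sequence(
    length=1000, gc_content=0.6, target_ratio=0.8, seed=1)
cgi_density = cpg.cpg_obs_exp_ratio(cgi_seq)
print(f"simulated CGI promoter: length={cgi_density.length}  "
      f"n_CpG={cgi_density.n_cpg}  ratio={cgi_density.ratio:.3f}  "
      f"class={cpg.classify_cgi(cgi_density)}")

print("\nA low ratio (<0.6) marks a CpG-poor promoter: few CpGs relative to "
      "its C/G content, hence methylatable and, in this regulatory model, "
      "inducible.")
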