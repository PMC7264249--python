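"""Target-gene set algebra and TF co-binding classification.

Reproduces the bound-gene x DEG intersection logic on the published
worked-example sizes (two stimulation conditions with 475 and 118 targets
sharing 70 genes; 237 previously reported), then shows the strict <200 bp
summit-distance co-binding rule.
"""

from sekit.core import Peak
from sekit.targets import cobinding, novel_vs_reported, summarize_sets

# --- set algebra on the worked-example sizes ---
cond_a = {f"g{i}" for i in range(475)}          # targets, condition A
cond_b = {f"g{i}" for i in range(405, 523)}     # targets, condition B
s = summarize_sets(cond_a, cond_b)
print(f"|A|={s.n_a} |B|={s.n_b} shared={s.n_intersection} union={s.n_union}")

reported = {f"g{i}" for i in range(237)}
union = cond_a | cond_b
n_rep, n_novel = novel_vs_reported(union, reported)
print(f"previously reported: {n_rep}, novel: {n_novel}")

# --- co-binding: summit distance strictly below 200 bp merges ---
def summit_peak(pos, name):
    return Peak.from_coords("chr1", pos - 50, pos + 50, name, summit=pos)

a = [summit_peak(1_000, "tfA_1"), summit_peak(10_000, "tfA_2")]
b = [summit_peak(1_199, "tfB_1"), summit_peak(10_200, "tfB_2")]
res = cobinding(a, b, max_dist=200)
print(f"co-bound pairs: {[(pa.name, pb.name) for pa, pb in res.pairs]}")
print(f"unique to A: {[p.name for p in res.a_only]}, "
      f"unique to B: {[p.name for p in res.b_only]}")
# 199 bp apart -> co-bound; 200 bp apart -> the rule is strict, so both
# peaks stay unique to their set.
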