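# 51-point avatar scheme -> canonical 22-point scheme, version 1.
# canonical_index: target index in the 22-point scheme.
# source / donor_a,donor_b: names in the 51-point scheme.  A row with a
# single source is a direct copy; a row with two donors is synthesized
# as the midpoint of the donors (three canonical points have no direct
# correspondent in the 51-point scheme: the two nose-saddle points and
# the outer middle of the upper lip).
canonical_index,source,donor_a,donor_b
1,left eyebrow outer,,
2,left eyebrow mid,,
3,left eyebrow inner,,
4,right eyebrow inner,,
5,right eyebrow mid,,
6,right eyebrow outer,,
7,left eye outer corner,,
8,left eye inner corner,,
9,right eye inner corner,,
10,right eye outer corner,,
11,,left eyebrow inner,left eye inner corner
12,,right eyebrow inner,right eye inner corner
13,nose wing left,,
14,nose tip,,
15,nose wing right,,
16,mouth corner left,,
17,,upper lip peak left,upper lip peak right
18,mouth corner right,,
19,inner lip upper middle,,
20,inner lip lower middle,,
21,outer lip lower middle,,
22,chin middle,,
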