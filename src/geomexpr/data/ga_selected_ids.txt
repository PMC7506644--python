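# The 47 descriptors retained by the best genetic-algorithm fit
# (wrapper selection with cubic-SVM cross-validated fitness).
# One id per line, grouped as in the feature catalog.
2D3
4D3
6D3
8D3
9D3
10D3
11D3
12D3
13D3
14D3
16D3
18D3
2A3
3A3
4A3
5A3
7A3
11A3
12A3
15A3
19A3
21A3
23A3
24A3
26A3
27A3
1D2
2D2
4D2
5D2
7D2
10D2
12D2
14D2
16D2
17D2
19D2
20D2
21D2
5A2
9A2
10A2
12A2
14A2
15A2
18A2
20A2
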