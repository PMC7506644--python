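id,kind,space,p1,p2,p3
1D3,distance,3D,1,3,
2D3,distance,3D,4,6,
3D3,distance,3D,3,8,
4D3,distance,3D,4,9,
5D3,distance,3D,8,22,
6D3,distance,3D,9,22,
7D3,distance,3D,18,16,
8D3,distance,3D,17,21,
9D3,distance,3D,16,7,
10D3,distance,3D,10,18,
11D3,distance,3D,14,11,
12D3,distance,3D,14,12,
13D3,distance,3D,22,2,
14D3,distance,3D,22,5,
15D3,distance,3D,9,18,
16D3,distance,3D,8,16,
17D3,distance,3D,17,16,
18D3,distance,3D,17,18,
19D3,distance,3D,19,20,
1A3,angle,3D,1,2,3
2A3,angle,3D,4,5,6
3A3,angle,3D,2,1,7
4A3,angle,3D,10,6,5
5A3,angle,3D,16,17,18
6A3,angle,3D,16,21,18
7A3,angle,3D,13,14,15
8A3,angle,3D,17,16,1
9A3,angle,3D,17,18,6
10A3,angle,3D,16,22,18
11A3,angle,3D,19,16,20
12A3,angle,3D,19,18,20
13A3,angle,3D,8,16,21
14A3,angle,3D,9,18,21
15A3,angle,3D,8,16,17
16A3,angle,3D,9,18,17
17A3,angle,3D,1,3,8
18A3,angle,3D,9,4,6
19A3,angle,3D,2,3,8
20A3,angle,3D,5,4,9
21A3,angle,3D,1,7,8
22A3,angle,3D,6,10,9
23A3,angle,3D,16,21,22
24A3,angle,3D,18,21,22
25A3,angle,3D,3,14,4
26A3,angle,3D,7,8,2
27A3,angle,3D,10,9,5
1D2,distance,2D,1,3,
2D2,distance,2D,4,6,
3D2,distance,2D,3,8,
4D2,distance,2D,4,9,
5D2,distance,2D,8,13,
6D2,distance,2D,9,15,
7D2,distance,2D,18,16,
8D2,distance,2D,17,21,
9D2,distance,2D,3,4,
10D2,distance,2D,16,22,
11D2,distance,2D,18,22,
12D2,distance,2D,7,16,
13D2,distance,2D,10,18,
14D2,distance,2D,17,14,
15D2,distance,2D,7,22,
16D2,distance,2D,10,22,
17D2,distance,2D,14,11,
18D2,distance,2D,14,12,
19D2,distance,2D,9,21,
20D2,distance,2D,8,21,
21D2,distance,2D,22,2,
22D2,distance,2D,22,5,
23D2,distance,2D,19,20,
1A2,angle,2D,1,2,3
2A2,angle,2D,4,5,6
3A2,angle,2D,16,17,18
4A2,angle,2D,16,21,18
5A2,angle,2D,17,16,21
6A2,angle,2D,17,18,21
7A2,angle,2D,17,16,1
8A2,angle,2D,17,18,6
9A2,angle,2D,3,8,11
10A2,angle,2D,4,9,12
11A2,angle,2D,19,16,20
12A2,angle,2D,19,18,20
13A2,angle,2D,1,7,8
14A2,angle,2D,6,10,9
15A2,angle,2D,7,8,3
16A2,angle,2D,4,9,10
17A2,angle,2D,7,8,2
18A2,angle,2D,10,9,5
19A2,angle,2D,8,16,21
20A2,angle,2D,9,18,21
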