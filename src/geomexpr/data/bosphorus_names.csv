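file_name,canonical_index
Outer left eyebrow,1
Middle left eyebrow,2
Inner left eyebrow,3
Inner right eyebrow,4
Middle right eyebrow,5
Outer right eyebrow,6
Outer left eye corner,7
Inner left eye corner,8
Inner right eye corner,9
Outer right eye corner,10
Nose saddle left,11
Nose saddle right,12
Left nose peak,13
Nose tip,14
Right nose peak,15
Left mouth corner,16
Upper lip outer middle,17
Right mouth corner,18
Upper lip inner middle,19
Lower lip inner middle,20
Lower lip outer middle,21
Chin middle,22
Left ear lobe,0
Right ear lobe,0
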