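>SYNKB01.1 NFKB
A  [  1  2  1 14  2  2  2  2  1  1 ]
C  [  1  2  2  2 14  2  2  2 16 16 ]
G  [ 17 14 16  2  2  2  2  2  2  2 ]
T  [  1  2  1  2  2 14 14 14  1  1 ]
>SYNKB02.1 REL
A  [  1  2  1 14 14 14  2  2  1  1 ]
C  [  1  2  2  2  2  2  2  2 16 16 ]
G  [ 17 14 16  2  2  2  2  2  2  2 ]
T  [  1  2  1  2  2  2 14 14  1  1 ]
>SYNKB03.1 p50
A  [  1  2  1  2 14  2  2  2  1  1 ]
C  [  1  2  2  2  2  2  2 14 16 16 ]
G  [ 17 14 16 14  2  2  2  2  2  2 ]
T  [  1  2  1  2  2 14 14  2  1  1 ]
>SYNKB04.1 p65
A  [  1  2  1 14  2  2  2  2  1  1 ]
C  [  1  2  2  2  2  2  2 14 16 16 ]
G  [ 17 14 16  2  2  2  2  2  2  2 ]
T  [  1  2  1  2 14 14 14  2  1  1 ]
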