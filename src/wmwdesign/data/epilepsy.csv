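group,value
1,3
1,3
1,5
1,4
1,21
1,7
1,2
1,12
1,5
1,0
1,22
1,4
1,2
1,12
1,9
1,5
1,3
1,29
1,5
1,7
1,4
1,4
1,5
1,8
1,25
1,1
1,2
1,12
2,1
2,1
2,2
2,2
2,10
2,3
2,1
2,6
2,2
2,0
2,11
2,2
2,1
2,6
2,4
2,2
2,1
2,14
2,2
2,3
2,2
2,2
2,2
2,4
2,12
2,0
2,1
2,6
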