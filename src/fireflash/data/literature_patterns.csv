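species,state,duration_s
P. bethaniensis,on,0.27
P. bethaniensis,off,0.53
P. bethaniensis,on,0.27
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. carolinus,off,0.37
P. carolinus,on,0.23
P. forresti,on,0.16
P. forresti,off,0.1
P. forresti,on,0.16
P. forresti,off,0.1
P. forresti,on,0.16
P. forresti,off,0.1
P. forresti,on,0.16
P. forresti,off,0.1
P. forresti,on,0.16
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. frontalis,off,0.87
P. frontalis,on,0.13
P. knulli,on,0.2
P. knulli,off,0.32
P. knulli,on,0.2
P. knulli,off,0.32
P. knulli,on,0.2
P. obscurellus,on,0.22
P. obscurellus,off,0.28
P. obscurellus,on,0.22
P. obscurellus,off,0.28
P. obscurellus,on,0.22
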