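# Idealized (synthetic) iron-sulfur binding module: 17 Ca trace + 2Fe-2S cluster.
# Not derived from any deposited coordinates.
kind,index,x,y,z
CA,1,8.000,0.000,-4.000
CA,2,7.127,3.634,-3.500
CA,3,4.699,6.475,-3.000
CA,4,1.245,7.903,-2.500
CA,5,-2.480,7.606,-2.000
CA,6,-5.664,5.649,-1.500
CA,7,-7.612,2.460,-1.000
CA,8,-7.899,-1.266,-0.500
CA,9,-6.462,-4.716,0.000
CA,10,-3.615,-7.137,0.500
CA,11,0.022,-8.000,1.000
CA,12,3.653,-7.117,1.500
CA,13,6.487,-4.681,2.000
CA,14,7.906,-1.224,2.500
CA,15,7.599,2.501,3.000
CA,16,5.634,5.680,3.500
CA,17,2.439,7.619,4.000
FE,0,1.350,0.000,0.000
FE,0,-1.350,0.000,0.000
S,0,0.000,1.730,0.000
S,0,0.000,-1.730,0.000
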