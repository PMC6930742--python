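region_name,hemisphere,x,y,z,radius_mm,also_reported_as
ventromedial prefrontal cortex,right,2,21,-15,5,
dorsomedial prefrontal cortex,right,2,38,39,5,
superior temporal gyrus,right,52,-41,13,5,
superior temporal gyrus,right,51,-4,-2,5,
superior temporal gyrus,right,46,-15,-6,5,middle temporal gyrus
superior temporal gyrus,right,51,-6,-9,5,middle temporal gyrus
superior temporal gyrus,right,59,-1,-4,5,
cingulate gyrus,right,4,49,-5,5,
cingulate gyrus,right,10,30,22,5,
cingulate gyrus,right,5,-55,28,5,
middle temporal gyrus,right,48,-58,6,5,
middle temporal gyrus,right,63,5,-17,5,
middle temporal gyrus,right,49,-70,13,5,
parahippocampal gyrus,right,14,5,-17,5,
parahippocampal gyrus,right,37,-35,-15,5,
inferior temporal gyrus,right,47,-32,-17,5,
inferior temporal gyrus,right,55,-23,-24,5,
rostral middle frontal gyrus,right,37,51,9,5,
rostral middle frontal gyrus,right,16,21,-17,5,
inferior parietal lobule,right,44,-63,39,5,
inferior parietal lobule,right,43,-66,25,5,
inferior parietal lobule,right,46,-56,44,5,
insula,right,36,3,1,5,
insula,right,39,1,1,5,
superior temporal gyrus BA41,right,43,-30,10,5,
cuneus,right,5,-77,16,5,
transverse temporal gyrus,right,43,-24,3,5,
pars orbitalis,right,45,-55,43,5,
supramarginal gyrus,right,59,-40,24,5,
supramarginal gyrus,right,57,-57,27,5,
occipital lobe,right,1,-84,-3,5,
hypothalamus,right,5,-5,-11,5,
superior frontal gyrus,right,11,18,59,5,
middle frontal gyrus,right,48,35,20,5,
inferior frontal gyrus,right,50,19,-12,5,
superior temporal gyrus,left,-46,-34,10,5,
superior temporal gyrus,left,-63,-6,1,5,
superior temporal gyrus,left,-44,-12,-11,5,middle temporal gyrus
superior temporal gyrus,left,-58,-16,6,5,
superior temporal gyrus,left,-48,9,-25,5,
superior temporal gyrus,left,-47,8,-26,5,
cingulate gyrus,left,-14,23,-13,5,
cingulate gyrus,left,-20,5,43,5,
cingulate gyrus,left,-4,-43,29,5,
parahippocampal gyrus,left,-20,2,-23,5,
inferior temporal gyrus,left,-62,-12,-26,5,
inferior temporal gyrus,left,-44,-50,-12,5,
inferior temporal gyrus,left,-45,-50,-12,5,
rostral middle frontal gyrus,left,-20,56,-2,5,
rostral middle frontal gyrus,left,-23,54,16,5,
rostral middle frontal gyrus,left,-20,55,-3,5,
superior frontal gyrus,left,-7,27,55,5,
superior frontal gyrus,left,-7,52,36,5,
superior frontal gyrus,left,-11,63,19,5,
superior frontal gyrus,left,-12,65,6,5,
superior temporal gyrus BA41,left,-42,-23,10,5,
transverse temporal gyrus,left,-51,-21,4,5,
hypothalamus,left,-4,-10,-6,5,
middle frontal gyrus,left,-36,35,28,5,
inferior frontal gyrus,left,-10,63,8,5,
postcentral gyrus,left,-32,-31,61,5,
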