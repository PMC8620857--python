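metabolite,lod_pmole,cv_percent,linear_range_pmole,r_squared,mass_error_ppm
2-phosphoglycerate,0.0254,10.8,0.229-1000,0.98729,0.54
6-phosphogluconate,0.076,10.7,0.229-500,0.9993,0
a-ketoglutarate,0.685,15.8,2.06-1500,0.99622,0.69
L-alanine,6.15,20.9,6.15-1500,0.99199,2.27
L-aspartate,0.076,9.15,0.229-1500,0.99862,0
cis-aconitate,0.0254,39.3,0.0760-166.5,0.99015,0.58
DHAP,18.5,33.2,18.5-1500,0.99815,0.59
sedoheptulose 7P,0.076,12.8,0.229-500,0.9981,0.69
fructose-13C6,0.0254,12,0.0254-166.5,0.99749,0.54
fructose-1-6-BP,0.0254,17.6,0.0254-1500,0.99259,0.59
fructose-1P,0.0254,9.62,0.0760-1500,0.99408,0
fructose-6P,0.0254,12.8,0.0760-1500,0.99078,0
fumarate,0.685,11.3,2.06-1500,0.98993,0
glucose,0.685,13.8,2.06-1500,0.98751,0.56
glucose-1P,0.0254,12.3,0.0760-500,0.9955,0
glucose-6P,0.0254,11.4,0.0760-500,0.99585,0
glutamate,0.0254,8.95,0.229-3000,0.99572,-0.68
glutamine,0.076,6.85,0.229-1500,0.99001,-0.69
glyceraldehyde-3P,55.5,5.45,55.5-1500,0.98939,0.59
glycine,18.5,4.71,18.5-1500,0.99478,0
glyecrol-3P,0.076,7.95,0.229-500,0.99723,0.58
isocitrate,6.15,31.6,6.15-500,0.96498,0.52
lactate,0.229,z12.4,0.229-55.5,0.98791,0
malate,0.076,39.2,0.229-166.5,0.99544,0.75
myo-inositol-d6,6.15,15.1,6.15-1500,0.9838,0.54
phosphoenolpyruvate,0.076,14.3,0.229-1500,0.99564,0.6
pyruvate,2.06,18.9,2.06-1000,0.96721,0
ribulose-5P,0.685,9.84,0.685-1000,0.98069,-0.44
serine,0.229,9.88,0.229-1500,0.99155,0.96
sorbitol,0.076,11.2,0.229-500,0.99293,0
succinate,0.229,12.2,2.06-1000,0.96498,0
UDP-glucose,0.229,12.1,0.229-1500,0.99135,1.77
xylitol-13C5,0.229,9.35,2.06-1000,0.98754,0.64
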