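species,clade,gs_pg,fd_cm
actinia,Passiflora,1.057,6.33
alata,Passiflora,2.208,12.52
caerulea,Passiflora,1.386,6.37
campanulata,Passiflora,1.195,6.62
caparidifolia,Passiflora,2.051,12.8
cerasina,Passiflora,1.319,7.53
coccinea,Passiflora,1.337,10.11
edmundoii,Passiflora,0.760,6.32
edulis,Passiflora,1.258,6.94
eischleriana,Passiflora,1.212,6.57
foetida,Passiflora,0.481,3.49
galbana,Passiflora,1.386,7.13
gardinerii,Passiflora,1.918,7.03
gibertii,Passiflora,1.710,6.82
hatschbachi,Passiflora,0.881,6.89
incarnata,Passiflora,0.659,6.9
iodocarpa,Passiflora,1.299,7.18
ischnoclada,Passiflora,0.901,5.51
jilekii,Passiflora,0.933,3.93
kermesina,Passiflora,1.237,7.81
ligularis,Passiflora,1.414,6.36
loefgrenii,Passiflora,1.310,6.34
miersii,Passiflora,1.452,6.46
mucronata,Passiflora,1.512,7.1
nitida,Passiflora,1.849,10.39
palmeri,Passiflora,0.263,3.81
picturata,Passiflora,2.172,8.02
platyloba,Passiflora,1.643,5.53
pilosicorona,Passiflora,1.400,10.95
racemosa,Passiflora,1.076,8.73
serratodigitata,Passiflora,1.387,8.3
sidaefolia,Passiflora,0.928,6.04
subrotunda,Passiflora,1.318,4.99
urubiscencis,Passiflora,1.582,6.27
vitifolia,Passiflora,1.414,11.87
watsoniana,Passiflora,1.305,6.14
auriculata,Decaloba,0.993,2.86
capsularis,Decaloba,0.319,2.86
leptoclada,Decaloba,0.261,2.75
micropelata,Decaloba,0.250,3.94
misera,Decaloba,0.253,2.72
morifolia,Decaloba,0.505,2.91
organensis,Decaloba,0.212,2.68
pohlii,Decaloba,0.299,2.5
suberosa,Decaloba,0.684,1.42
tricuspis,Decaloba,0.287,2.7
truncata,Decaloba,0.704,2.48
tulae,Decaloba,0.277,4.41
vespertilio,Decaloba,0.327,3.76
deidamioides,outgroup,0.815,4.69
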