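entity,year,axis,value
core,1949,1,0.45
core,1949,2,0.38
core,1949,3,0.32
core,1974,1,0.64
core,1974,2,0.71
core,1974,3,0.24
core,1999,1,0.55
core,1999,2,0.66
core,1999,3,0.41
core,2016,1,0.52
core,2016,2,0.68
core,2016,3,0.39
islet,1949,1,-0.89
islet,1949,2,0.30
islet,1949,3,0.01
islet,1974,1,-0.51
islet,1974,2,0.60
islet,1974,3,-0.45
islet,1999,1,-0.82
islet,1999,2,0.20
islet,1999,3,0.32
islet,2016,1,-0.82
islet,2016,2,0.20
islet,2016,3,0.32
perforation,1949,1,0.69
perforation,1949,2,0.17
perforation,1949,3,0.15
perforation,1974,1,0.69
perforation,1974,2,0.27
perforation,1974,3,0.43
perforation,1999,1,0.70
perforation,1999,2,0.43
perforation,1999,3,0.28
perforation,2016,1,0.75
perforation,2016,2,0.42
perforation,2016,3,0.35
edge,1949,1,-0.77
edge,1949,2,0.48
edge,1949,3,-0.33
edge,1974,1,-0.86
edge,1974,2,0.42
edge,1974,3,0.08
edge,1999,1,-0.82
edge,1999,2,0.17
edge,1999,3,0.51
edge,2016,1,-0.83
edge,2016,2,0.21
edge,2016,3,0.46
loop,1949,1,-0.11
loop,1949,2,0.36
loop,1949,3,-0.86
loop,1974,1,-0.27
loop,1974,2,0.60
loop,1974,3,-0.73
loop,1999,1,0.61
loop,1999,2,0.02
loop,1999,3,-0.47
loop,2016,1,0.54
loop,2016,2,0.30
loop,2016,3,-0.59
bridge,1949,1,0.55
bridge,1949,2,0.36
bridge,1949,3,0.11
bridge,1974,1,0.35
bridge,1974,2,0.82
bridge,1974,3,-0.28
bridge,1999,1,0.76
bridge,1999,2,0.31
bridge,1999,3,-0.14
bridge,2016,1,0.74
bridge,2016,2,0.14
bridge,2016,3,-0.30
branch,1949,1,-0.76
branch,1949,2,0.26
branch,1949,3,-0.14
branch,1974,1,-0.84
branch,1974,2,0.47
branch,1974,3,0.26
branch,1999,1,-0.78
branch,1999,2,0.01
branch,1999,3,-0.18
branch,2016,1,-0.84
branch,2016,2,0.47
branch,2016,3,0.26
built_up,1949,1,1.5
built_up,1949,2,-0.9
built_up,1949,3,0.8
built_up,1974,1,1.8
built_up,1974,2,0.0
built_up,1974,3,1.7
built_up,1999,1,1.6
built_up,1999,2,0.5
built_up,1999,3,0.4
built_up,2016,1,1.6
built_up,2016,2,0.3
built_up,2016,3,0.3
urban_green,1949,1,-2.8
urban_green,1949,2,2.3
urban_green,1949,3,-2.6
urban_green,1974,1,-3.2
urban_green,1974,2,6.5
urban_green,1974,3,-3.4
urban_green,1999,1,-1.7
urban_green,1999,2,0.0
urban_green,1999,3,0.6
urban_green,2016,1,-2.1
urban_green,2016,2,0.9
urban_green,2016,3,1.0
arable,1949,1,2.8
arable,1949,2,0.6
arable,1949,3,2.1
arable,1974,1,2.8
arable,1974,2,0.8
arable,1974,3,1.4
arable,1999,1,1.6
arable,1999,2,0.8
arable,1999,3,0.2
arable,2016,1,1.6
arable,2016,2,0.4
arable,2016,3,-0.1
crop_mosaic,1949,1,-0.1
crop_mosaic,1949,2,-0.8
crop_mosaic,1949,3,-0.2
crop_mosaic,1974,1,-0.1
crop_mosaic,1974,2,-2.5
crop_mosaic,1974,3,-0.1
crop_mosaic,1999,1,0.2
crop_mosaic,1999,2,-0.9
crop_mosaic,1999,3,-0.9
crop_mosaic,2016,1,-0.4
crop_mosaic,2016,2,-1.0
crop_mosaic,2016,3,-0.6
vineyards,1949,1,0.8
vineyards,1949,2,-0.6
vineyards,1949,3,0.3
vineyards,1974,1,-0.1
vineyards,1974,2,-0.7
vineyards,1974,3,-0.3
vineyards,1999,1,0.7
vineyards,1999,2,-0.5
vineyards,1999,3,-0.7
vineyards,2016,1,0.6
vineyards,2016,2,-1.0
vineyards,2016,3,-1.3
olive_groves,1949,1,-2.2
olive_groves,1949,2,0.4
olive_groves,1949,3,2.3
olive_groves,1974,1,-0.6
olive_groves,1974,2,-1.8
olive_groves,1974,3,-1.1
olive_groves,1999,1,-0.9
olive_groves,1999,2,-1.1
olive_groves,1999,3,-1.0
olive_groves,2016,1,0.3
olive_groves,2016,2,-1.0
olive_groves,2016,3,-1.3
woodland,1949,1,1.3
woodland,1949,2,-0.1
woodland,1949,3,0.4
woodland,1974,1,1.9
woodland,1974,2,1.1
woodland,1974,3,0.3
woodland,1999,1,3.3
woodland,1999,2,2.1
woodland,1999,3,0.2
woodland,2016,1,2.8
woodland,2016,2,2.1
woodland,2016,3,-0.4
pastures,1949,1,1.2
pastures,1949,2,-0.7
pastures,1949,3,0.8
pastures,1974,1,0.2
pastures,1974,2,-1.9
pastures,1974,3,-0.4
pastures,1999,1,-0.7
pastures,1999,2,-0.9
pastures,1999,3,-1.2
pastures,2016,1,0.0
pastures,2016,2,-1.0
pastures,2016,3,-1.1
wetlands,1949,1,-2.3
wetlands,1949,2,-0.2
wetlands,1949,3,0.7
wetlands,1974,1,-2.6
wetlands,1974,2,-1.7
wetlands,1974,3,1.9
wetlands,1999,1,-4.1
wetlands,1999,2,-0.1
wetlands,1999,3,2.5
wetlands,2016,1,-4.4
wetlands,2016,2,0.4
wetlands,2016,3,3.4
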