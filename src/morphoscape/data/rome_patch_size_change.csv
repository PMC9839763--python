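stage,function,structure,annual_change_ha
urbanisation,built_up,core,0.12
urbanisation,urban_green,core,-0.11
urbanisation,arable,core,-1.5
urbanisation,crop_mosaic,core,-0.1
urbanisation,vineyards,core,-0.74
urbanisation,olive_groves,core,-0.14
urbanisation,woodland,core,0.36
urbanisation,pastures,core,-0.06
urbanisation,wetlands,core,-0.4
urbanisation,built_up,islet,0.09
urbanisation,urban_green,islet,0.01
urbanisation,arable,islet,0.03
urbanisation,crop_mosaic,islet,0.04
urbanisation,vineyards,islet,0.08
urbanisation,olive_groves,islet,-0.05
urbanisation,woodland,islet,0.05
urbanisation,pastures,islet,0.0
urbanisation,wetlands,islet,-0.16
urbanisation,built_up,perforation,0.09
urbanisation,urban_green,perforation,0.0
urbanisation,arable,perforation,0.08
urbanisation,crop_mosaic,perforation,0.0
urbanisation,vineyards,perforation,-0.05
urbanisation,olive_groves,perforation,0.0
urbanisation,woodland,perforation,-0.22
urbanisation,pastures,perforation,-0.27
urbanisation,wetlands,perforation,0.0
urbanisation,built_up,edge,-0.02
urbanisation,urban_green,edge,-0.37
urbanisation,arable,edge,0.04
urbanisation,crop_mosaic,edge,-0.05
urbanisation,vineyards,edge,-0.14
urbanisation,olive_groves,edge,-0.22
urbanisation,woodland,edge,-0.08
urbanisation,pastures,edge,-0.05
urbanisation,wetlands,edge,0.0
urbanisation,built_up,loop,0.0
urbanisation,urban_green,loop,0.4
urbanisation,arable,loop,0.0
urbanisation,crop_mosaic,loop,-0.06
urbanisation,vineyards,loop,-0.08
urbanisation,olive_groves,loop,0.0
urbanisation,woodland,loop,0.03
urbanisation,pastures,loop,0.06
urbanisation,wetlands,loop,0.0
urbanisation,built_up,bridge,0.05
urbanisation,urban_green,bridge,0.34
urbanisation,arable,bridge,-0.37
urbanisation,crop_mosaic,bridge,-0.08
urbanisation,vineyards,bridge,0.1
urbanisation,olive_groves,bridge,0.15
urbanisation,woodland,bridge,0.21
urbanisation,pastures,bridge,-0.06
urbanisation,wetlands,bridge,0.0
urbanisation,built_up,branch,0.0
urbanisation,urban_green,branch,-0.04
urbanisation,arable,branch,0.0
urbanisation,crop_mosaic,branch,-0.02
urbanisation,vineyards,branch,0.0
urbanisation,olive_groves,branch,-0.06
urbanisation,woodland,branch,-0.02
urbanisation,pastures,branch,-0.01
urbanisation,wetlands,branch,0.0
suburbanisation,built_up,core,-0.22
suburbanisation,urban_green,core,-0.42
suburbanisation,arable,core,-0.79
suburbanisation,crop_mosaic,core,-0.11
suburbanisation,vineyards,core,-0.47
suburbanisation,olive_groves,core,-0.06
suburbanisation,woodland,core,-0.24
suburbanisation,pastures,core,-0.19
suburbanisation,wetlands,core,0.1
suburbanisation,built_up,islet,-0.07
suburbanisation,urban_green,islet,-0.17
suburbanisation,arable,islet,-0.02
suburbanisation,crop_mosaic,islet,-0.04
suburbanisation,vineyards,islet,-0.06
suburbanisation,olive_groves,islet,-0.07
suburbanisation,woodland,islet,-0.06
suburbanisation,pastures,islet,-0.04
suburbanisation,wetlands,islet,0.02
suburbanisation,built_up,perforation,-0.11
suburbanisation,urban_green,perforation,0.0
suburbanisation,arable,perforation,-0.04
suburbanisation,crop_mosaic,perforation,0.0
suburbanisation,vineyards,perforation,0.0
suburbanisation,olive_groves,perforation,0.0
suburbanisation,woodland,perforation,0.25
suburbanisation,pastures,perforation,0.0
suburbanisation,wetlands,perforation,0.0
suburbanisation,built_up,edge,-0.15
suburbanisation,urban_green,edge,-0.33
suburbanisation,arable,edge,-0.07
suburbanisation,crop_mosaic,edge,-0.08
suburbanisation,vineyards,edge,-0.24
suburbanisation,olive_groves,edge,-0.19
suburbanisation,woodland,edge,-0.07
suburbanisation,pastures,edge,-0.1
suburbanisation,wetlands,edge,0.0
suburbanisation,built_up,loop,0.03
suburbanisation,urban_green,loop,-0.78
suburbanisation,arable,loop,0.03
suburbanisation,crop_mosaic,loop,0.16
suburbanisation,vineyards,loop,-0.02
suburbanisation,olive_groves,loop,-0.3
suburbanisation,woodland,loop,0.15
suburbanisation,pastures,loop,0.04
suburbanisation,wetlands,loop,0.0
suburbanisation,built_up,bridge,0.08
suburbanisation,urban_green,bridge,-0.34
suburbanisation,arable,bridge,0.38
suburbanisation,crop_mosaic,bridge,0.18
suburbanisation,vineyards,bridge,0.62
suburbanisation,olive_groves,bridge,0.15
suburbanisation,woodland,bridge,0.42
suburbanisation,pastures,bridge,0.08
suburbanisation,wetlands,bridge,0.0
suburbanisation,built_up,branch,-0.01
suburbanisation,urban_green,branch,-0.02
suburbanisation,arable,branch,0.0
suburbanisation,crop_mosaic,branch,0.01
suburbanisation,vineyards,branch,-0.01
suburbanisation,olive_groves,branch,0.01
suburbanisation,woodland,branch,0.0
suburbanisation,pastures,branch,0.01
suburbanisation,wetlands,branch,-0.02
counter_urbanisation,built_up,core,-0.09
counter_urbanisation,urban_green,core,0.0
counter_urbanisation,arable,core,-0.06
counter_urbanisation,crop_mosaic,core,0.02
counter_urbanisation,vineyards,core,-0.02
counter_urbanisation,olive_groves,core,0.05
counter_urbanisation,woodland,core,-0.03
counter_urbanisation,pastures,core,-0.01
counter_urbanisation,wetlands,core,0.0
counter_urbanisation,built_up,islet,0.0
counter_urbanisation,urban_green,islet,0.01
counter_urbanisation,arable,islet,0.0
counter_urbanisation,crop_mosaic,islet,0.0
counter_urbanisation,vineyards,islet,-0.01
counter_urbanisation,olive_groves,islet,-0.01
counter_urbanisation,woodland,islet,0.0
counter_urbanisation,pastures,islet,-0.02
counter_urbanisation,wetlands,islet,0.0
counter_urbanisation,built_up,perforation,-0.03
counter_urbanisation,urban_green,perforation,0.0
counter_urbanisation,arable,perforation,0.0
counter_urbanisation,crop_mosaic,perforation,0.0
counter_urbanisation,vineyards,perforation,0.0
counter_urbanisation,olive_groves,perforation,0.0
counter_urbanisation,woodland,perforation,-0.19
counter_urbanisation,pastures,perforation,0.0
counter_urbanisation,wetlands,perforation,0.0
counter_urbanisation,built_up,edge,-0.03
counter_urbanisation,urban_green,edge,0.04
counter_urbanisation,arable,edge,0.01
counter_urbanisation,crop_mosaic,edge,0.02
counter_urbanisation,vineyards,edge,0.0
counter_urbanisation,olive_groves,edge,-0.04
counter_urbanisation,woodland,edge,0.0
counter_urbanisation,pastures,edge,-0.03
counter_urbanisation,wetlands,edge,0.0
counter_urbanisation,built_up,loop,-0.03
counter_urbanisation,urban_green,loop,0.09
counter_urbanisation,arable,loop,0.01
counter_urbanisation,crop_mosaic,loop,-0.21
counter_urbanisation,vineyards,loop,0.0
counter_urbanisation,olive_groves,loop,0.0
counter_urbanisation,woodland,loop,-0.04
counter_urbanisation,pastures,loop,0.05
counter_urbanisation,wetlands,loop,0.0
counter_urbanisation,built_up,bridge,0.08
counter_urbanisation,urban_green,bridge,-0.03
counter_urbanisation,arable,bridge,-0.02
counter_urbanisation,crop_mosaic,bridge,0.04
counter_urbanisation,vineyards,bridge,0.11
counter_urbanisation,olive_groves,bridge,0.44
counter_urbanisation,woodland,bridge,-0.13
counter_urbanisation,pastures,bridge,0.0
counter_urbanisation,wetlands,bridge,0.0
counter_urbanisation,built_up,branch,0.0
counter_urbanisation,urban_green,branch,0.0
counter_urbanisation,arable,branch,0.0
counter_urbanisation,crop_mosaic,branch,0.0
counter_urbanisation,vineyards,branch,0.01
counter_urbanisation,olive_groves,branch,0.0
counter_urbanisation,woodland,branch,0.0
counter_urbanisation,pastures,branch,-0.01
counter_urbanisation,wetlands,branch,-0.01
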