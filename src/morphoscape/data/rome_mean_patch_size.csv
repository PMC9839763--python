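year,function,structure,mean_patch_size_ha
1949,built_up,core,20.3
1949,urban_green,core,23.3
1949,arable,core,73.2
1949,crop_mosaic,core,6.7
1949,vineyards,core,33.1
1949,olive_groves,core,6.4
1949,woodland,core,21.8
1949,pastures,core,8.6
1949,wetlands,core,15.0
1949,built_up,islet,0.9
1949,urban_green,islet,6.8
1949,arable,islet,1.5
1949,crop_mosaic,islet,2.2
1949,vineyards,islet,1.5
1949,olive_groves,islet,4.6
1949,woodland,islet,2.0
1949,pastures,islet,3.3
1949,wetlands,islet,7.1
1949,built_up,perforation,6.0
1949,urban_green,perforation,0.0
1949,arable,perforation,3.4
1949,crop_mosaic,perforation,0.0
1949,vineyards,perforation,1.3
1949,olive_groves,perforation,0.0
1949,woodland,perforation,10.0
1949,pastures,perforation,6.7
1949,wetlands,perforation,0.0
1949,built_up,edge,9.0
1949,urban_green,edge,26.6
1949,arable,edge,3.6
1949,crop_mosaic,edge,8.6
1949,vineyards,edge,12.2
1949,olive_groves,edge,13.9
1949,woodland,edge,7.8
1949,pastures,edge,7.6
1949,wetlands,edge,15.0
1949,built_up,loop,5.3
1949,urban_green,loop,15.0
1949,arable,loop,4.8
1949,crop_mosaic,loop,7.5
1949,vineyards,loop,7.5
1949,olive_groves,loop,15.0
1949,woodland,loop,8.2
1949,pastures,loop,5.0
1949,wetlands,loop,0.0
1949,built_up,bridge,6.7
1949,urban_green,bridge,10.4
1949,arable,bridge,24.0
1949,crop_mosaic,bridge,7.5
1949,vineyards,bridge,6.2
1949,olive_groves,bridge,0.0
1949,woodland,bridge,8.4
1949,pastures,bridge,9.8
1949,wetlands,bridge,0.0
1949,built_up,branch,1.1
1949,urban_green,branch,2.9
1949,arable,branch,0.7
1949,crop_mosaic,branch,1.5
1949,vineyards,branch,1.2
1949,olive_groves,branch,2.9
1949,woodland,branch,1.7
1949,pastures,branch,1.5
1949,wetlands,branch,2.5
1974,built_up,core,23.3
1974,urban_green,core,20.7
1974,arable,core,35.7
1974,crop_mosaic,core,4.3
1974,vineyards,core,14.4
1974,olive_groves,core,2.9
1974,woodland,core,30.7
1974,pastures,core,7.2
1974,wetlands,core,5.0
1974,built_up,islet,3.2
1974,urban_green,islet,7.0
1974,arable,islet,2.4
1974,crop_mosaic,islet,3.1
1974,vineyards,islet,3.5
1974,olive_groves,islet,3.4
1974,woodland,islet,3.3
1974,pastures,islet,3.2
1974,wetlands,islet,3.1
1974,built_up,perforation,8.2
1974,urban_green,perforation,0.0
1974,arable,perforation,5.5
1974,crop_mosaic,perforation,0.0
1974,vineyards,perforation,0.0
1974,olive_groves,perforation,0.0
1974,woodland,perforation,4.5
1974,pastures,perforation,0.0
1974,wetlands,perforation,0.0
1974,built_up,edge,8.5
1974,urban_green,edge,17.3
1974,arable,edge,4.5
1974,crop_mosaic,edge,7.4
1974,vineyards,edge,8.6
1974,olive_groves,edge,8.4
1974,woodland,edge,5.9
1974,pastures,edge,6.4
1974,wetlands,edge,15.0
1974,built_up,loop,5.2
1974,urban_green,loop,25.0
1974,arable,loop,4.6
1974,crop_mosaic,loop,6.0
1974,vineyards,loop,5.4
1974,olive_groves,loop,15.0
1974,woodland,loop,9.0
1974,pastures,loop,6.5
1974,wetlands,loop,0.0
1974,built_up,bridge,7.9
1974,urban_green,bridge,19.0
1974,arable,bridge,14.8
1974,crop_mosaic,bridge,5.4
1974,vineyards,bridge,8.9
1974,olive_groves,bridge,3.7
1974,woodland,bridge,13.7
1974,pastures,bridge,8.2
1974,wetlands,bridge,0.0
1974,built_up,branch,1.1
1974,urban_green,branch,2.0
1974,arable,branch,0.7
1974,crop_mosaic,branch,1.1
1974,vineyards,branch,1.2
1974,olive_groves,branch,1.4
1974,woodland,branch,1.1
1974,pastures,branch,1.2
1974,wetlands,branch,2.5
1999,built_up,core,17.8
1999,urban_green,core,10.2
1999,arable,core,15.9
1999,crop_mosaic,core,1.6
1999,vineyards,core,2.6
1999,olive_groves,core,1.4
1999,woodland,core,24.5
1999,pastures,core,2.4
1999,wetlands,core,7.5
1999,built_up,islet,1.4
1999,urban_green,islet,2.7
1999,arable,islet,1.8
1999,crop_mosaic,islet,2.1
1999,vineyards,islet,2.0
1999,olive_groves,islet,1.8
1999,woodland,islet,1.8
1999,pastures,islet,2.3
1999,wetlands,islet,3.7
1999,built_up,perforation,5.5
1999,urban_green,perforation,0.0
1999,arable,perforation,4.4
1999,crop_mosaic,perforation,0.0
1999,vineyards,perforation,0.0
1999,olive_groves,perforation,0.0
1999,woodland,perforation,10.7
1999,pastures,perforation,0.0
1999,wetlands,perforation,0.0
1999,built_up,edge,4.7
1999,urban_green,edge,8.9
1999,arable,edge,2.7
1999,crop_mosaic,edge,5.4
1999,vineyards,edge,2.7
1999,olive_groves,edge,3.7
1999,woodland,edge,4.2
1999,pastures,edge,4.0
1999,wetlands,edge,15.0
1999,built_up,loop,5.9
1999,urban_green,loop,5.4
1999,arable,loop,5.3
1999,crop_mosaic,loop,10.0
1999,vineyards,loop,5.0
1999,olive_groves,loop,7.5
1999,woodland,loop,12.8
1999,pastures,loop,7.6
1999,wetlands,loop,0.0
1999,built_up,bridge,9.8
1999,urban_green,bridge,10.6
1999,arable,bridge,24.3
1999,crop_mosaic,bridge,10.0
1999,vineyards,bridge,24.3
1999,olive_groves,bridge,7.5
1999,woodland,bridge,24.3
1999,pastures,bridge,10.1
1999,wetlands,bridge,0.0
1999,built_up,branch,0.9
1999,urban_green,branch,1.6
1999,arable,branch,0.7
1999,crop_mosaic,branch,1.3
1999,vineyards,branch,0.9
1999,olive_groves,branch,1.5
1999,woodland,branch,1.1
1999,pastures,branch,1.6
1999,wetlands,branch,2.1
2016,built_up,core,16.3
2016,urban_green,core,10.1
2016,arable,core,14.9
2016,crop_mosaic,core,1.9
2016,vineyards,core,2.3
2016,olive_groves,core,2.1
2016,woodland,core,24.0
2016,pastures,core,2.3
2016,wetlands,core,7.5
2016,built_up,islet,1.5
2016,urban_green,islet,2.8
2016,arable,islet,1.8
2016,crop_mosaic,islet,2.1
2016,vineyards,islet,1.8
2016,olive_groves,islet,1.5
2016,woodland,islet,1.8
2016,pastures,islet,2.0
2016,wetlands,islet,3.8
2016,built_up,perforation,5.0
2016,urban_green,perforation,0.0
2016,arable,perforation,4.3
2016,crop_mosaic,perforation,0.0
2016,vineyards,perforation,0.0
2016,olive_groves,perforation,0.0
2016,woodland,perforation,7.5
2016,pastures,perforation,0.0
2016,wetlands,perforation,0.0
2016,built_up,edge,4.1
2016,urban_green,edge,9.6
2016,arable,edge,2.8
2016,crop_mosaic,edge,5.7
2016,vineyards,edge,2.8
2016,olive_groves,edge,3.0
2016,woodland,edge,4.3
2016,pastures,edge,3.5
2016,wetlands,edge,15.0
2016,built_up,loop,5.5
2016,urban_green,loop,6.9
2016,arable,loop,5.5
2016,crop_mosaic,loop,6.4
2016,vineyards,loop,5.0
2016,olive_groves,loop,7.5
2016,woodland,loop,12.1
2016,pastures,loop,8.5
2016,wetlands,loop,0.0
2016,built_up,bridge,11.1
2016,urban_green,bridge,10.0
2016,arable,bridge,23.9
2016,crop_mosaic,bridge,10.7
2016,vineyards,bridge,26.2
2016,olive_groves,bridge,15.0
2016,woodland,bridge,22.1
2016,pastures,bridge,10.1
2016,wetlands,bridge,0.0
2016,built_up,branch,0.9
2016,urban_green,branch,1.6
2016,arable,branch,0.8
2016,crop_mosaic,branch,1.2
2016,vineyards,branch,1.0
2016,olive_groves,branch,1.5
2016,woodland,branch,1.2
2016,pastures,branch,1.4
2016,wetlands,branch,2.0
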