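typology,land_cover,reclass,group,area_ha
forest_seminatural,Rocky outcrops,"Others (rocky outcrops, glaciers)",Total others,257.81
forest_seminatural,Natural sandy areas,"Others (rocky outcrops, glaciers)",Total others,287.51
forest_seminatural,Glacial and snow zones,"Others (rocky outcrops, glaciers)",Total others,66.12
forest_seminatural,Natural shrublands,Natural shrublands,Natural shrublands,39627.44
forest_seminatural,Natural grasslands (Paramo),Natural grasslands (Paramo),Natural grasslands (Paramo),87665.07
forest_seminatural,Dense forest,Dense forest,Total primary forest,117687.30
forest_seminatural,Riparian forest,Riparian forest,Total primary forest,2487.41
forest_seminatural,Fragmented forests,Secondary forest,Total secondary forest,29330.82
forest_seminatural,Secondary vegetation or in transition,Secondary vegetation or in transition,Total secondary forest,48542.91
agricultural,Permanent woody crops,Permanent woody crops,Total permanent crops,3635.33
agricultural,Permanent herbaceous crops,Sugarcane plantations,Total permanent crops,192742.20
agricultural,Pasture and forest mosaic,Pasture and forest mosaic,Total agricultural mosaics,75165.72
agricultural,Cropland mosaic,Cropland mosaic,Total agricultural mosaics,1922.57
agricultural,Cropland and forest mosaic,Cropland and forest mosaic,Total agricultural mosaics,18478.08
agricultural,"Cropland, forest, and pasture mosaic","Cropland, forest, and pasture mosaic",Total agricultural mosaics,152551.30
agricultural,Cropland and pasture mosaic,Cropland and pasture mosaic,Total agricultural mosaics,64564.77
agricultural,Wooded pastures,Wooded pastures,Total pastures,4673.74
agricultural,Weeded pastures,Weeded pastures,Total pastures,41797.32
agricultural,Clean pastures,Clean pastures,Total pastures,84076.29
agricultural,Timber plantations,Timber plantations,Timber plantations,3238.40
water,Rivers (50 m),Rivers and natural water bodies,Total water,2569.59
water,Artificial water bodies,Artificial water bodies,Total water,1637.38
water,"Lagoons, lakes, swamps, and natural swamps",Rivers and natural water bodies,Total water,527.56
built,Continuous urban fabric (Urban areas),Urban areas,Total urban and industrial areas,16228.67
built,Discontinuous urban fabric (Suburban areas),Urban areas,Total urban and industrial areas,3447.70
built,Industrial or commercial areas (Industrial area),Urban areas,Total urban and industrial areas,4278.26
other,Nude and degraded soils,Nude soils,Nude soils,854.29
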